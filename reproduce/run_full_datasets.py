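#!/usr/bin/env python
"""Full-dataset training/benchmark driver (requires downloaded data).

See reproduce/README.md for the inputs this script expects. It performs
no downloads itself: every structure, PQR, DSSP and PSSM file must be
present locally.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np


def _find(directory: Path | None, stem: str, suffix: str) -> str | None:
    if directory is None:
        return None
    p = directory / f"{stem}{suffix}"
    return str(p) if p.exists() else None


def load_set(list_file: Path, structures: Path, pssm: Path | None,
             dssp: Path | None, pqr: Path | None, cutoff: float):
    from rbres.annotate import AnnotationConfig, annotate_complex
    from rbres.structure import assign_charges, read_chain_list, read_complex

    config = AnnotationConfig(binding_cutoff=cutoff)
    annotations = []
    skipped = []
    for pdb_id, chain_id in read_chain_list(list_file):
        stem = f"{pdb_id}_{chain_id}"
        pdb_path = structures / f"{pdb_id}.pdb"
        if not pdb_path.exists():
            pdb_path = structures / f"{stem}.pdb"
        if not pdb_path.exists():
            skipped.append((stem, "structure missing"))
            continue
        try:
            cx = read_complex(pdb_path, protein_chains=[chain_id])
            assign_charges(cx, _find(pqr, stem, ".pqr"))
            pssm_path = _find(pssm, stem, ".pssm")
            anns = annotate_complex(
                cx, config,
                pssm_sources={chain_id: pssm_path} if pssm_path else None,
                dssp_path=_find(dssp, stem, ".dssp"),
            )
        except Exception as exc:  # noqa: BLE001 - per-chain failures reported
            skipped.append((stem, str(exc)))
            continue
        annotations.extend(anns)
    return annotations, skipped


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--train-list", type=Path, required=True)
    parser.add_argument("--test-list", type=Path)
    parser.add_argument("--structures", type=Path, required=True)
    parser.add_argument("--pssm", type=Path)
    parser.add_argument("--dssp", type=Path)
    parser.add_argument("--pqr", type=Path)
    parser.add_argument("--cutoff", type=float, default=5.0)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    from rbres.encoding import encode_dataset
    from rbres.evaluation import CvPlan, ablation, cross_validate, \
        evaluate_predictions
    from rbres.estimators import RnaBindingForest
    from rbres.propensity import build_table_from_stats, save_table

    args.out.mkdir(parents=True, exist_ok=True)
    train, skipped = load_set(args.train_list, args.structures, args.pssm,
                              args.dssp, args.pqr, args.cutoff)
    if skipped:
        (args.out / "skipped.txt").write_text(
            "\n".join(f"{s}\t{why}" for s, why in skipped))
    table = build_table_from_stats([a.stats() for a in train],
                                   provenance={"cutoff": args.cutoff})
    save_table(table, args.out / "propensity.json")
    X, y, layout = encode_dataset(train, table)

    plan = CvPlan(k=5, seed=args.seed)
    cv = cross_validate(X, y, plan)
    (args.out / "cv_metrics.json").write_text(json.dumps(
        {"pooled": cv.pooled.as_dict(), "macro": cv.macro}, indent=1))
    ablation(X, y, layout, plan).to_csv(args.out / "ablation.tsv", sep="\t")

    if args.test_list:
        test, skipped_t = load_set(args.test_list, args.structures, args.pssm,
                                   args.dssp, args.pqr, args.cutoff)
        Xt, yt, _ = encode_dataset(test, table)
        clf = RnaBindingForest(random_state=args.seed).fit(X, y)
        probs = clf.predict_proba(Xt)[:, 1]
        rep = evaluate_predictions(probs, yt)
        (args.out / "benchmark_metrics.json").write_text(
            json.dumps(rep.as_dict(), indent=1))
        np.savetxt(args.out / "benchmark_probabilities.tsv",
                   np.column_stack([probs, yt.astype(int)]),
                   header="probability\tlabel", fmt="%.5f\t%d")
    print(f"done; outputs under {args.out}")


if __name__ == "__main__":
    main()
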