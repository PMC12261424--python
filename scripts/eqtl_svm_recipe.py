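#!/usr/bin/env python
"""Variant-effect classification recipe over exported embeddings.

This is a thin, documented recipe — not a core library operation —
because its real inputs (eQTL labels and transcription-start-site
annotations) are external. It consumes:

* an embeddings table as written by ``probgenome embed``
  (``id`` column + one column per embedding dimension), and
* a metadata table with columns ``id``, ``label`` (0/1 causal effect),
  and ``tss_distance`` (bp to the nearest transcription start site).

Variants are stratified into TSS-distance buckets (0-30 kb, 30-100 kb,
100 kb+). Per bucket, up to 5000 training samples are drawn, an SVM with
an RBF kernel is fit, and the AUROC is recorded on the held-out
remainder; the draw is repeated 5 times and the mean per-bucket AUROC is
reported.

Usage:
    python scripts/eqtl_svm_recipe.py --embeddings emb.tsv \
        --metadata meta.tsv --seed 0 [--per-bucket 5000] [--repeats 5]
"""

from __future__ import annotations

import argparse

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

BUCKETS = (("0-30k", 0, 30_000),
           ("30k-100k", 30_000, 100_000),
           ("100k+", 100_000, np.inf))


def bucket_auroc(X, y, per_bucket, repeats, seed):
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(repeats):
        idx = rng.permutation(len(y))
        train = idx[:min(per_bucket, len(idx) // 2)]
        test = idx[len(train):]
        if len(set(y[train])) < 2 or len(set(y[test])) < 2:
            continue
        clf = SVC(kernel="rbf")
        clf.fit(X[train], y[train])
        scores.append(roc_auc_score(y[test],
                                    clf.decision_function(X[test])))
    return float(np.mean(scores)) if scores else float("nan")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--embeddings", required=True)
    parser.add_argument("--metadata", required=True)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--per-bucket", type=int, default=5000)
    parser.add_argument("--repeats", type=int, default=5)
    args = parser.parse_args()

    emb = pd.read_csv(args.embeddings, sep="\t")
    meta = pd.read_csv(args.metadata, sep="\t")
    merged = emb.merge(meta, on="id")
    feature_cols = [c for c in emb.columns if c != "id"]

    results = []
    for name, lo, hi in BUCKETS:
        sub = merged[(merged.tss_distance >= lo)
                     & (merged.tss_distance < hi)]
        if len(sub) < 4:
            results.append((name, float("nan")))
            continue
        auroc = bucket_auroc(sub[feature_cols].to_numpy(),
                             sub["label"].to_numpy(),
                             args.per_bucket, args.repeats, args.seed)
        results.append((name, auroc))
    for name, auroc in results:
        print(f"{name}\t{auroc:.4f}")
    valid = [a for _, a in results if not np.isnan(a)]
    if valid:
        print(f"average\t{np.mean(valid):.4f}")


if __name__ == "__main__":
    main()
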