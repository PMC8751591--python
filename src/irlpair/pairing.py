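"""Binary lncRNA-pair encoding and the effective-match filter.

For an ordered pair (A, B) and sample s the indicator is

    alpha_s = 1  if expression(A, s) > expression(B, s)  (strictly)
            = 0  otherwise (ties count as 0).

Because alpha depends only on which of the two genes is higher within
the sample, the pair matrix — and everything built on it — is invariant
to any strictly increasing transform of the expression values.

A pair is an *effective match* when neither indicator class dominates:
the fraction of ones must lie strictly inside (low, high), by default
(0.2, 0.8), i.e. neither the 0-class nor the 1-class reaches 80% of
samples. Pairs are enumerated lexicographically with gene_a < gene_b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from irlpair.io_formats import ExpressionMatrix

PAIR_SEP = "|"


def pair_id(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}{PAIR_SEP}{gene_b}"


def split_pair_id(pid: str) -> tuple[str, str]:
    a, _, b = pid.partition(PAIR_SEP)
    return a, b


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Orient a pair with the lexicographically smaller gene first."""
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


@dataclass
class PairIndicatorMatrix:
    """pair x sample binary indicators with per-pair one-fractions.

    ``indicators`` is indexed by pair id "geneA|geneB" (gene_a
    lexicographically first); ``one_fraction`` is the per-pair mean
    indicator; ``n_candidates`` the pair count before the effective-match
    filter.
    """

    indicators: pd.DataFrame
    one_fraction: pd.Series
    n_candidates: int

    @property
    def pair_ids(self) -> list[str]:
        return list(self.indicators.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicators.columns)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [split_pair_id(p) for p in self.indicators.index]


def encode_pair(expr_a, expr_b) -> np.ndarray:
    """Per-sample indicator: 1 where ``expr_a`` strictly exceeds ``expr_b``."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return (a > b).astype(np.int8)


def build_effective_pairs(
    expr: ExpressionMatrix,
    low: float = 0.2,
    high: float = 0.8,
) -> PairIndicatorMatrix:
    """Enumerate all unordered gene pairs and keep the effective matches.

    ``expr`` should already be restricted to the differentially expressed
    lncRNAs. All C(n, 2) pairs are generated in lexicographic gene order;
    a pair survives iff its one-fraction lies strictly in (low, high).
    """
    genes = sorted(expr.gene_ids)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    if expr.values.shape[1] < 1:
        raise ValueError("need at least 1 sample")
    vals = expr.values.loc[genes].to_numpy(dtype=float)
    n = len(genes)
    rows, ids = [], []
    for i in range(n - 1):
        # vectorised over the j > i block
        alpha = (vals[i][None, :] > vals[i + 1 :]).astype(np.int8)
        frac = alpha.mean(axis=1)
        keep = (frac > low) & (frac < high)
        for k in np.nonzero(keep)[0]:
            ids.append(pair_id(genes[i], genes[i + 1 + k]))
            rows.append(alpha[k])
    n_candidates = n * (n - 1) // 2
    indicators = pd.DataFrame(
        np.asarray(rows, dtype=np.int8).reshape(len(rows), len(expr.sample_ids)),
        index=pd.Index(ids, name="pair"),
        columns=expr.values.columns,
    )
    one_fraction = indicators.mean(axis=1)
    return PairIndicatorMatrix(indicators, one_fraction, n_candidates)
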