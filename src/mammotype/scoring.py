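"""Per-sample gene-signature Z-scores and group comparisons.

A signature score for a sample is the mean, over the signature's genes,
of the gene's standardized expression (value minus the across-sample mean,
divided by the across-sample SD, n-1 denominator).  Scores for signatures
such as adhesion, EMT, luminalness, proliferation, vascular content,
immunosuppression and interferons are compared between tumor groups with
two-tailed Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidLabelsError, MissingGeneError, SignatureError
from .stats import GroupComparison, wilcoxon_rank_sum

__all__ = [
    "GeneSignature",
    "SignatureScore",
    "zscore_signature",
    "single_gene_contrast",
    "compare_scores",
]


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty list of unique gene identifiers."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise SignatureError(f"signature {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if list(self.gene_ids).count(g) > 1})
            raise SignatureError(f"signature {self.name!r} has duplicate genes: {dupes}")


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    signature_name: str
    score: float
    n_genes_used: int


def zscore_signature(matrix: pd.DataFrame, signature: GeneSignature) -> list[SignatureScore]:
    """Score each sample as the mean standardized expression over the
    signature's genes present in the matrix.

    Genes absent from the matrix are dropped; genes with zero SD across
    samples carry no information and are excluded (with a warning), both
    reflected in ``n_genes_used``.
    """
    if matrix.shape[1] < 2:
        raise SignatureError("scoring requires >= 2 samples")
    present = [g for g in signature.gene_ids if g in matrix.index]
    if not present:
        raise SignatureError(f"no gene of signature {signature.name!r} is in the matrix")
    sub = matrix.loc[present]
    sds = sub.std(axis=1, ddof=1)
    usable = sds > 0
    if not usable.any():
        raise SignatureError(
            f"all genes of signature {signature.name!r} are constant across samples"
        )
    if (~usable).any():
        warnings.warn(
            f"signature {signature.name!r}: {int((~usable).sum())} zero-SD gene(s) excluded"
        )
    sub = sub.loc[usable]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sds[usable], axis=0)
    scores = z.mean(axis=0)
    n_used = int(usable.sum())
    return [
        SignatureScore(str(s), signature.name, float(scores[s]), n_used)
        for s in matrix.columns
    ]


def _split_groups(labels: pd.Series) -> tuple[str, str]:
    groups = sorted(pd.unique(labels.dropna()))
    if len(groups) != 2:
        raise InvalidLabelsError(f"exactly 2 groups required, got {groups}")
    return groups[0], groups[1]


def single_gene_contrast(
    matrix: pd.DataFrame, gene_up: str, gene_down: str, labels: pd.Series
) -> dict:
    """Two-group contrast of a putatively up- and down-regulated gene pair
    (e.g. Cd44 up / Cd24a down in claudin-low-like tumors).

    For each gene, a two-tailed Wilcoxon rank-sum test between groups and
    the direction of the median difference.
    """
    for g in (gene_up, gene_down):
        if g not in matrix.index:
            raise MissingGeneError(f"gene {g!r} not in the expression matrix")
    ga, gb = _split_groups(labels)
    out = {}
    for g in (gene_up, gene_down):
        x = matrix.loc[g, labels.index[labels == ga]].to_numpy(dtype=float)
        y = matrix.loc[g, labels.index[labels == gb]].to_numpy(dtype=float)
        comp = wilcoxon_rank_sum(x, y, group_names=(str(ga), str(gb)))
        med_diff = float(np.median(x) - np.median(y))
        direction = f"up in {ga}" if med_diff > 0 else (f"up in {gb}" if med_diff < 0 else "equal")
        out[g] = {"comparison": comp, "p_value": comp.p_value,
                  "median_difference": med_diff, "direction": direction}
    return out


def compare_scores(scores: list[SignatureScore], labels: pd.Series) -> dict[str, GroupComparison]:
    """Per-signature two-tailed Wilcoxon rank-sum test of scores between two groups.

    ``labels`` maps sample id -> group; both groups must be non-empty.
    """
    ga, gb = _split_groups(labels)
    df = pd.DataFrame(
        [(s.sample_id, s.signature_name, s.score) for s in scores],
        columns=["sample_id", "signature", "score"],
    )
    df["group"] = df["sample_id"].map(labels)
    results = {}
    for sig, sub in df.groupby("signature"):
        x = sub.loc[sub["group"] == ga, "score"].to_numpy()
        y = sub.loc[sub["group"] == gb, "score"].to_numpy()
        if x.size == 0 or y.size == 0:
            raise InvalidLabelsError(f"signature {sig!r}: a group has no scored samples")
        results[sig] = wilcoxon_rank_sum(x, y, group_names=(str(ga), str(gb)))
    return results
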