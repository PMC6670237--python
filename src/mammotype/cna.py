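"""Gene-level copy-number aberration characterization.

CNA input is a gene-by-tumor integer status matrix on a 5-level code:
-2 homozygous deletion, -1 heterozygous deletion, 0 neutral, 1 single-copy
gain, 2 multi-copy amplification (segmentation itself is upstream of this
pipeline; a BED-like segment-to-gene projection helper is provided).

Operations: per-tumor CNA burden (non-neutral gene count and amplified
fraction), potential-driver calls by intersecting aberrations with cancer
gene census alteration types, pairwise profile similarity to surface
near-identical tumor pairs, and two-group burden comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IncomparableProfilesError, InvalidInputError, InvalidLabelsError
from .stats import GroupComparison, wilcoxon_rank_sum

__all__ = [
    "CNA_LEVELS",
    "validate_profiles",
    "cna_burden",
    "driver_cnas",
    "profile_similarity",
    "compare_burden",
    "segments_to_gene_status",
]

CNA_LEVELS = (-2, -1, 0, 1, 2)


def validate_profiles(profiles: pd.DataFrame | pd.Series) -> None:
    """Check the 5-level status code."""
    values = np.asarray(profiles, dtype=int)
    if not np.isin(values, CNA_LEVELS).all():
        bad = sorted(set(values.ravel()) - set(CNA_LEVELS))
        raise InvalidInputError(f"CNA statuses outside {CNA_LEVELS}: {bad}")


def cna_burden(profile: pd.Series) -> dict:
    """Number of genes with non-neutral status, plus the amplified fraction
    (statuses > 0 among non-neutral genes; NaN for an all-neutral profile)."""
    validate_profiles(profile)
    nonzero = profile[profile != 0]
    burden = int(len(nonzero))
    amp_fraction = float((nonzero > 0).mean()) if burden else float("nan")
    return {"burden": burden, "amplified_fraction": amp_fraction}


def driver_cnas(
    profile: pd.Series,
    census: pd.DataFrame,
    amp_threshold: int = 1,
    del_threshold: int = -1,
) -> pd.DataFrame:
    """Potential driver CNA calls for one tumor.

    A gene is called iff its status reaches ``amp_threshold`` and the census
    lists amplification for it, or its status reaches ``del_threshold`` and
    the census lists deletion.  The default thresholds count any gain/loss
    (+-1); a strict mode uses (2, -2).  Census columns: ``gene``, ``role``,
    ``alteration`` (comma-separated subsets of oncogene/TSG and
    amplification/deletion).
    """
    validate_profiles(profile)
    if not {"gene", "alteration"}.issubset(census.columns):
        raise InvalidInputError("census table needs 'gene' and 'alteration' columns")
    calls = []
    alt = census.set_index("gene")["alteration"].astype(str)
    for gene, kinds in alt.items():
        if gene not in profile.index:
            continue
        status = int(profile[gene])
        kindset = {k.strip() for k in kinds.split(",")}
        if status >= amp_threshold and "amplification" in kindset:
            calls.append((gene, status, "amplification"))
        elif status <= del_threshold and "deletion" in kindset:
            calls.append((gene, status, "deletion"))
    return pd.DataFrame(calls, columns=["gene", "status", "event"])


def profile_similarity(profiles: pd.DataFrame) -> dict:
    """Pairwise similarity between tumor CNA profiles.

    ``profiles`` is a gene-by-tumor status matrix over a shared gene
    universe.  Similarity is (a) the fraction of genes with identical
    status and (b) the Jaccard index of the non-neutral gene sets; pairs
    are ranked by the identical-status fraction (used to surface sets of
    tumors with remarkably similar profiles).
    """
    if profiles.shape[1] < 2:
        raise InvalidInputError("need >= 2 profiles")
    if profiles.shape[0] == 0:
        raise IncomparableProfilesError("profiles share no gene universe")
    validate_profiles(profiles)
    X = profiles.to_numpy(dtype=int)
    tumors = list(profiles.columns)
    n = len(tumors)
    ident = np.ones((n, n))
    jacc = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = float((X[:, i] == X[:, j]).mean())
            nz_i, nz_j = X[:, i] != 0, X[:, j] != 0
            union = int((nz_i | nz_j).sum())
            jac = float((nz_i & nz_j).sum() / union) if union else 1.0
            ident[i, j] = ident[j, i] = same
            jacc[i, j] = jacc[j, i] = jac
    pairs = [
        (tumors[i], tumors[j], ident[i, j], jacc[i, j])
        for i in range(n) for j in range(i + 1, n)
    ]
    ranked = (
        pd.DataFrame(pairs, columns=["tumor_a", "tumor_b", "identical_fraction", "jaccard"])
        .sort_values("identical_fraction", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return {
        "identical_fraction": pd.DataFrame(ident, index=tumors, columns=tumors),
        "jaccard": pd.DataFrame(jacc, index=tumors, columns=tumors),
        "ranked_pairs": ranked,
    }


def compare_burden(profiles: pd.DataFrame, labels: pd.Series) -> dict:
    """Two-group comparison of per-tumor CNA burdens (two-tailed rank-sum).

    Returns group means and the GroupComparison.
    """
    groups = sorted(pd.unique(labels.dropna()))
    if len(groups) != 2:
        raise InvalidLabelsError(f"exactly 2 groups required, got {groups}")
    burdens = pd.Series(
        {t: cna_burden(profiles[t])["burden"] for t in profiles.columns}, dtype=float
    )
    ga, gb = groups
    x = burdens[labels.index[labels == ga]].to_numpy()
    y = burdens[labels.index[labels == gb]].to_numpy()
    if x.size == 0 or y.size == 0:
        raise InvalidLabelsError("both groups must be non-empty")
    comp = wilcoxon_rank_sum(x, y, group_names=(str(ga), str(gb)))
    return {
        "means": {str(ga): float(x.mean()), str(gb): float(y.mean())},
        "comparison": comp,
        "p_value": comp.p_value,
    }


def segments_to_gene_status(
    segments: pd.DataFrame, genes: pd.DataFrame
) -> pd.Series:
    """Project BED-like CNA segments onto genes (0-based half-open intervals).

    ``segments``: columns chrom, start, end, status; ``genes``: columns
    chrom, start, end, gene.  A gene takes the status of the segment with
    the largest overlap; genes with no overlapping segment are neutral (0).
    """
    for df, cols in ((segments, {"chrom", "start", "end", "status"}),
                     (genes, {"chrom", "start", "end", "gene"})):
        if not cols.issubset(df.columns):
            raise InvalidInputError(f"expected columns {sorted(cols)}")
    status = {}
    segs_by_chrom = dict(tuple(segments.groupby("chrom")))
    for _, g in genes.iterrows():
        segs = segs_by_chrom.get(g["chrom"])
        best_overlap, best_status = 0, 0
        if segs is not None:
            overlap = (
                np.minimum(segs["end"], g["end"]) - np.maximum(segs["start"], g["start"])
            )
            if (overlap > 0).any():
                k = int(overlap.idxmax())
                best_overlap = int(overlap.loc[k])
                if best_overlap > 0:
                    best_status = int(segs.loc[k, "status"])
        status[g["gene"]] = best_status
    out = pd.Series(status, name="status")
    validate_profiles(out)
    return out
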