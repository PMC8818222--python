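"""Between-sample normalization and FPKM quantification.

Linear genes are normalized with TMM (trimmed mean of M-values) computed
from the linear count matrix and converted to FPKM on exon-union lengths.
circRNAs are quantified with a circRNA-specific effective length — twice
the read length minus twice the anchor size, the only junction-spanning
window in which a read is unbiased evidence for the circle — and share the
*linear* library size and TMM factor of the same sample, so circular and
linear abundance are on one comparable scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FPKM_SCALE = 1e9  # per kilobase of length, per million fragments


def circ_effective_length(read_length: int, anchor_size: int) -> int:
    """Effective length of every circRNA: 2 * (read_length - anchor_size)."""
    if read_length <= anchor_size:
        raise ValueError(
            f"read_length ({read_length}) must exceed anchor_size ({anchor_size})"
        )
    return 2 * (read_length - anchor_size)


def exon_union_length(gene_model) -> int:
    """Total exon length: the measure of the union of exon intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(gene_model.exons):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _quantile75(col: np.ndarray, lib: float) -> float:
    return float(np.quantile(col / lib, 0.75))


def choose_reference(counts: pd.DataFrame) -> str:
    """Reference column for TMM: upper quartile closest to the mean UQ."""
    libs = counts.sum(axis=0).to_numpy(float)
    f75 = np.array(
        [_quantile75(counts.iloc[:, i].to_numpy(float), libs[i])
         for i in range(counts.shape[1])]
    )
    return counts.columns[int(np.argmin(np.abs(f75 - f75.mean())))]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Unscaled TMM factor of one sample against the reference.

    M-values (log ratios) and A-values (log abundances) are computed over
    genes nonzero in both samples; the top and bottom trim_m of M and
    trim_a of A are discarded; the surviving M are averaged with inverse
    asymptotic-binomial-variance weights, and the factor is 2**mean.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # degenerate: identical proportions give M == 0 everywhere
    if np.allclose(m, 0.0):
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    w = 1.0 / (
        (lib_obs - obs[keep2]) / (lib_obs * obs[keep2])
        + (lib_ref - ref[keep2]) / (lib_ref * ref[keep2])
    )
    return float(2 ** (np.sum(w * m[keep2]) / np.sum(w)))


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    libs = counts.sum(axis=0)
    if (libs == 0).any():
        bad = list(libs.index[libs == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    if ref_sample is None:
        ref_sample = choose_reference(counts)
    elif ref_sample not in counts.columns:
        raise ValueError(f"unknown reference sample {ref_sample!r}")
    ref = counts[ref_sample].to_numpy(float)
    lib_ref = float(libs[ref_sample])
    factors = pd.Series(
        {
            s: _tmm_pair(
                counts[s].to_numpy(float), ref, float(libs[s]), lib_ref,
                trim_m, trim_a,
            )
            for s in counts.columns
        },
        name="norm_factor",
    )
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return factors


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    lib_size: pd.Series,
    norm_factor: pd.Series,
) -> pd.DataFrame:
    """FPKM(f, s) = count(f, s) * 1e9 / (length(f) * lib_size(s) * factor(s))."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])
        raise ValueError(f"missing lengths for {missing[:5]}...")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    missing = [s for s in counts.columns if s not in lib_size.index]
    if missing:
        raise ValueError(f"missing per-sample stats for {missing}")
    denom = np.outer(
        lengths.to_numpy(float),
        lib_size.reindex(counts.columns).to_numpy(float)
        * norm_factor.reindex(counts.columns).to_numpy(float),
    )
    return pd.DataFrame(
        counts.to_numpy(float) * FPKM_SCALE / denom,
        index=counts.index,
        columns=counts.columns,
    )


linear_fpkm = fpkm


def circ_fpkm(
    circ_counts: pd.DataFrame,
    read_length: int,
    anchor_size: int,
    lib_size: pd.Series,
    norm_factor: pd.Series,
) -> pd.DataFrame:
    """circRNA FPKM with the junction effective length and the same sample's
    linear library size and normalization factor in the denominator."""
    eff = circ_effective_length(read_length, anchor_size)
    lengths = pd.Series(eff, index=circ_counts.index, dtype=float)
    return fpkm(circ_counts, lengths, lib_size, norm_factor)


def circ_parent_ratio(
    circ_fpkm_mat: pd.DataFrame,
    linear_fpkm_mat: pd.DataFrame,
    gene_of_circ: dict,
) -> pd.DataFrame:
    """Ratio of each circRNA's FPKM to its parental gene's FPKM.

    Unannotated circRNAs are skipped; cells where the parent FPKM is 0 are
    NaN (undefined), never infinity.
    """
    rows = {}
    for circ in circ_fpkm_mat.index:
        gene = gene_of_circ.get(circ)
        if gene is None or gene == "unannotated" or gene not in linear_fpkm_mat.index:
            continue
        parent = linear_fpkm_mat.loc[gene].replace(0.0, np.nan)
        rows[circ] = circ_fpkm_mat.loc[circ] / parent
    out = pd.DataFrame(rows).T
    out.index.name = "junction_id"
    return out


def species_count(counts: pd.DataFrame, subset=None) -> pd.Series:
    """Detected-species count per sample: features with read count > 0.

    ``subset`` restricts to a feature list (e.g. the candidate panel, for
    the per-patient detection burden)."""
    mat = counts if subset is None else counts.reindex(subset).fillna(0)
    return (mat > 0).sum(axis=0).rename("n_species")
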