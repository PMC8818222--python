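"""Cross-compartment circRNA profiling statistics.

Compares CSF, plasma and tumor-tissue compartments: detected-species
counts, abundance distributions, shared-species counts within and between
patients, and the correlation / trend tests used on the clinical tables.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError


def shared_species(a: pd.Series, b: pd.Series) -> int:
    """Number of features detected (count > 0) in both samples."""
    a, b = a.align(b, join="inner")
    return int(((a > 0) & (b > 0)).sum())


def shared_species_threeway(a: pd.Series, b: pd.Series, c: pd.Series) -> int:
    a, b = a.align(b, join="inner")
    a, c = a.align(c, join="inner")
    b = b.reindex(a.index)
    return int(((a > 0) & (b > 0) & (c > 0)).sum())


def sharing_table(
    counts: pd.DataFrame, samples: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """All pairwise shared-species counts, log2-transformed with a pseudocount.

    ``samples`` must carry sample_id (index), patient_id and compartment.
    Returns one row per unordered sample pair with the pair's compartments,
    whether the two samples come from the same patient, the shared count
    and log2(shared + pseudocount).
    """
    rows = []
    for sa, sb in itertools.combinations(counts.columns, 2):
        n = shared_species(counts[sa], counts[sb])
        rows.append(
            {
                "sample_a": sa,
                "sample_b": sb,
                "patient_a": samples.loc[sa, "patient_id"],
                "patient_b": samples.loc[sb, "patient_id"],
                "compartment_a": samples.loc[sa, "compartment"],
                "compartment_b": samples.loc[sb, "compartment"],
                "same_patient": samples.loc[sa, "patient_id"]
                == samples.loc[sb, "patient_id"],
                "n_shared": n,
                "log2_shared": math.log2(n + pseudocount),
            }
        )
    return pd.DataFrame(rows)


def wilcoxon_test(x, y, paired: bool = False) -> tuple[float, float]:
    """Rank-based two-sample comparison.

    Paired: Wilcoxon signed-rank; unpaired: rank-sum (the statistic
    returned is the rank sum W of ``x``). Exact p-values for effective
    n <= 25 without ties, normal approximation with tie correction
    otherwise. Returns (statistic, two-sided p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal lengths")
        d = x - y
        d = d[d != 0]
        if d.size == 0:
            raise DegenerateDataError("all paired differences are zero")
        if d.size < 3:
            raise ValueError("need >= 3 nonzero differences")
        exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", mode="exact" if exact else "approx",
            correction=not exact,
        )
        return float(res.statistic), float(res.pvalue)
    if x.size < 3 or y.size < 3:
        raise ValueError("need >= 3 observations per group")
    pooled = np.concatenate([x, y])
    exact = pooled.size <= 25 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2  # U -> rank sum of x
    return w, float(res.pvalue)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r * sqrt(n-2) / sqrt(1-r^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def trend_over_lines(values, line_labels) -> tuple[float, float]:
    """Ordinal trend test across ordered therapy lines (Kendall tau-b).

    ``line_labels`` must be orderable (e.g. therapy-line number). Returns
    (tau, two-sided p)."""
    values = np.asarray(values, float)
    labels = np.asarray(line_labels)
    if np.unique(labels).size < 2:
        raise DegenerateDataError("need >= 2 ordered groups")
    if np.ptp(values) == 0:
        raise DegenerateDataError("constant values: trend undefined")
    tau, p = stats.kendalltau(labels, values)
    if np.isnan(tau):
        raise DegenerateDataError("trend statistic undefined")
    return float(tau), float(p)


def compartment_comparison_table(
    per_sample_values: pd.Series, samples: pd.DataFrame, paired: bool = False
) -> pd.DataFrame:
    """Pairwise compartment comparisons of a per-sample quantity.

    Unpaired by default: compartments have different availability per
    patient, so the rank-sum variant is the primary analysis; ``paired``
    restricts each comparison to patients with both samples and uses the
    signed-rank test.
    """
    rows = []
    comps = sorted(samples["compartment"].unique())
    for ca, cb in itertools.combinations(comps, 2):
        ids_a = samples.index[samples["compartment"] == ca]
        ids_b = samples.index[samples["compartment"] == cb]
        if paired:
            by_patient_a = dict(zip(samples.loc[ids_a, "patient_id"], ids_a))
            by_patient_b = dict(zip(samples.loc[ids_b, "patient_id"], ids_b))
            common = sorted(set(by_patient_a) & set(by_patient_b))
            va = per_sample_values.reindex(
                [by_patient_a[p] for p in common]
            ).to_numpy()
            vb = per_sample_values.reindex(
                [by_patient_b[p] for p in common]
            ).to_numpy()
        else:
            va = per_sample_values.reindex(ids_a).dropna().to_numpy()
            vb = per_sample_values.reindex(ids_b).dropna().to_numpy()
        stat, p = wilcoxon_test(va, vb, paired=paired)
        rows.append(
            {
                "group_a": ca,
                "group_b": cb,
                "n_a": len(va),
                "n_b": len(vb),
                "paired": paired,
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def percentage_table(counts: dict[str, int], n_total: int) -> pd.DataFrame:
    """Cohort-table helper: category counts -> rounded integer percentages."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    rows = [
        {"category": k, "n": v, "percent": round(100.0 * v / n_total)}
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows)
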