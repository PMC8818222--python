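"""Candidate-circRNA screening cascade and detection-burden dichotomization.

The cascade keeps a CSF-detected circRNA only if it (i) is not on the
normal-brain exclusion list and (ii) recurs in the tumor tissue of at
least ``min_patients`` distinct patients. Patients are then dichotomized
into circRNA-abundant vs circRNA-deficient groups by their candidate
detection burden (number of candidates detected in their CSF) at the
top-quantile nearest-rank cutoff.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import pandas as pd

from .chimeric import parse_junction_id
from .errors import ParseError

ABUNDANT = "abundant"
DEFICIENT = "deficient"


@dataclass
class ScreenReport:
    n_csf_total: int
    n_after_brain_exclusion: int
    n_after_tumor_recurrence: int
    candidates: list[str]
    per_patient_burden: dict[str, int] = field(default_factory=dict)
    cutoff: int | None = None
    groups: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def read_exclusion_list(path) -> set[str]:
    """Junction IDs from a TSV whose first column is the junction ID."""
    ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            jid = line.split("\t")[0]
            try:
                parse_junction_id(jid)
            except ParseError as exc:
                raise ParseError(f"bad junction ID {jid!r}", lineno) from exc
            ids.add(jid)
    return ids


def exclude_brain_list(csf_circ_ids, exclusion: set[str]) -> set[str]:
    """Remove circRNAs previously reported in normal brain tissue."""
    return set(csf_circ_ids) - set(exclusion)


def detected_patients(
    counts: pd.DataFrame, samples: pd.DataFrame, compartment: str
) -> pd.DataFrame:
    """Boolean circ x patient detection matrix within one compartment.

    A patient detects a circRNA if any of their samples in the compartment
    has count > 0."""
    ids = samples.index[samples["compartment"] == compartment]
    if len(ids) == 0:
        raise ValueError(f"no {compartment!r} samples in cohort")
    sub = counts.reindex(columns=ids).fillna(0)
    det = sub.gt(0)
    det.columns = samples.loc[ids, "patient_id"]
    return det.T.groupby(level=0).any().T


def tumor_recurrence_filter(
    counts: pd.DataFrame, samples: pd.DataFrame, min_patients: int = 2,
    compartment: str = "tissue",
) -> set[str]:
    """circRNAs detected in tumor tissue of >= min_patients distinct patients."""
    det = detected_patients(counts, samples, compartment)
    n_pat = det.sum(axis=1)
    return set(n_pat.index[n_pat >= min_patients])


def run_cascade(
    csf_counts: pd.DataFrame,
    tissue_counts: pd.DataFrame,
    samples: pd.DataFrame,
    exclusion: set[str],
    min_patients: int = 2,
) -> ScreenReport:
    """Run the screening cascade and report stage counts.

    Stage order is exclusion then tumor recurrence; the candidate set is an
    intersection, so the result is order-independent. Candidates are sorted
    lexicographically by junction ID.
    """
    csf_det = detected_patients(csf_counts, samples, "csf")
    csf_ids = set(csf_det.index[csf_det.any(axis=1)])
    after_excl = exclude_brain_list(csf_ids, exclusion)
    recurrent = tumor_recurrence_filter(tissue_counts, samples, min_patients)
    candidates = sorted(after_excl & recurrent)
    burden = candidate_burden(csf_counts, samples, candidates)
    return ScreenReport(
        n_csf_total=len(csf_ids),
        n_after_brain_exclusion=len(after_excl),
        n_after_tumor_recurrence=len(candidates),
        candidates=candidates,
        per_patient_burden=burden,
    )


def candidate_burden(
    csf_counts: pd.DataFrame, samples: pd.DataFrame, candidates
) -> dict[str, int]:
    """Per-patient count of candidates detected (count > 0) in their CSF."""
    det = detected_patients(csf_counts, samples, "csf")
    det = det.reindex(list(candidates)).fillna(False)
    return {str(p): int(det[p].sum()) for p in det.columns}


def dichotomize_burden(
    per_patient_burden: dict[str, int],
    quantile: float = 0.25,
    cutoff: int | None = None,
) -> tuple[int, dict[str, str], bool]:
    """Split patients at the top-``quantile`` burden cutoff.

    The cutoff is the (1 - quantile) empirical quantile under the
    nearest-rank definition (the ceil((1-quantile)*n)-th order statistic);
    burden <= cutoff is "deficient", > cutoff "abundant". An explicit
    ``cutoff`` overrides the quantile. Returns (cutoff, groups, degenerate)
    where degenerate flags a single-group split.
    """
    if len(per_patient_burden) < 2:
        raise ValueError("need >= 2 patients")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    burdens = sorted(per_patient_burden.values())
    if cutoff is None:
        k = math.ceil((1 - quantile) * len(burdens))
        cutoff = int(burdens[k - 1])
    groups = {
        p: (DEFICIENT if b <= cutoff else ABUNDANT)
        for p, b in per_patient_burden.items()
    }
    degenerate = len(set(groups.values())) < 2
    return cutoff, groups, degenerate


def screen(
    csf_counts: pd.DataFrame,
    tissue_counts: pd.DataFrame,
    samples: pd.DataFrame,
    exclusion: set[str],
    min_patients: int = 2,
    quantile: float = 0.25,
    cutoff: int | None = None,
) -> ScreenReport:
    """Full screen: cascade plus burden dichotomization."""
    report = run_cascade(
        csf_counts, tissue_counts, samples, exclusion, min_patients
    )
    report.cutoff, report.groups, report.degenerate = dichotomize_burden(
        report.per_patient_burden, quantile=quantile, cutoff=cutoff
    )
    return report
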