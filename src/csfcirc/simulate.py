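"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a paired CSF / plasma / tumor-tissue
circRNA cohort: CSF carries fewer circRNA species but at higher abundance,
with high inter-patient heterogeneity; a planted subset of "candidate"
circRNAs is shared between CSF and the tumor tissue of at least two
patients (and survives the screening cascade by construction); planted
miRNA binding sites span the back-splice junctions of candidate circles;
overall-survival hazard depends on each patient's candidate-detection
burden; and CSF ctDNA concentration is anti-correlated with circRNA
abundance.

Everything is driven by one integer seed; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import sponge
from .errors import InvalidConfigError
from .genes import GeneModel, write_bed12
from .chimeric import format_junction_id

BASES = np.array(list("ACGT"))

# stratum labels for the screening flowchart
CANDIDATE = "candidate"  # CSF-present, tumor-recurrent, not excluded
BRAIN_LISTED = "brain_listed"  # on the normal-brain exclusion list
CSF_NONRECURRENT = "csf_nonrecurrent"  # in CSF but tumor tissue of <= 1 patient
NON_CSF = "non_csf"  # never in CSF (plasma/tissue only)


@dataclass
class CohortConfig:
    n_patients: int = 21
    compartments: tuple = ("csf", "plasma", "tissue")
    # (patient_id, compartment) pairs absent; the default reproduces a
    # 19-CSF / 21-plasma / 15-tissue availability pattern.
    missing_samples: tuple = (
        ("P01", "csf"),
        ("P20", "csf"),
        ("P04", "tissue"),
        ("P07", "tissue"),
        ("P09", "tissue"),
        ("P11", "tissue"),
        ("P18", "tissue"),
        ("P19", "tissue"),
    )
    read_length: int = 150
    anchor_size: int = 20
    n_genes: int = 120
    n_circ_total: int = 300
    n_candidates_true: int = 12
    n_brain_listed: int = 60
    csf_species_fraction: float = 0.4
    csf_abundance_factor: float = 5.0
    hazard_ratio_abundant: float = 3.0
    abundant_fraction: float = 0.25
    coexpr_rho: float = 0.9
    ctdna_rho: float = -0.7
    decoys_per_sample: int = 20
    n_mirna_decoys: int = 20
    flank_nt: int = 30
    utr_length: int = 300
    mean_circ_count: float = 8.0
    mean_gene_count: float = 60.0
    dispersion: float = 0.3  # NB dispersion (1/size) for fluid compartments
    dispersion_tissue: float = 0.2
    median_os_months: float = 17.0
    max_followup_months: float = 40.0
    chrom_lengths: tuple = (("chr1", 400_000), ("chr2", 350_000), ("chr3", 250_000))
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        if self.n_patients < 2:
            raise InvalidConfigError("n_patients must be >= 2")
        if self.n_circ_total < self.n_candidates_true:
            raise InvalidConfigError("n_circ_total < n_candidates_true")
        if self.n_circ_total < self.n_candidates_true + self.n_brain_listed:
            raise InvalidConfigError("n_circ_total too small for the strata")
        if not 0 < self.csf_species_fraction < 1:
            raise InvalidConfigError("csf_species_fraction must be in (0, 1)")
        if self.csf_abundance_factor <= 1:
            raise InvalidConfigError("csf_abundance_factor must be > 1")
        if self.hazard_ratio_abundant <= 0:
            raise InvalidConfigError("hazard_ratio_abundant must be > 0")
        if self.read_length <= self.anchor_size:
            raise InvalidConfigError("read_length must exceed anchor_size")

    @property
    def patient_ids(self) -> list[str]:
        return [f"P{i:02d}" for i in range(1, self.n_patients + 1)]

    def sample_sheet(self) -> pd.DataFrame:
        missing = set(self.missing_samples)
        rows = []
        batches = "abcdef"
        i = 0
        for pid in self.patient_ids:
            for comp in self.compartments:
                if (pid, comp) in missing:
                    continue
                rows.append(
                    {
                        "sample_id": f"{pid}_{comp}",
                        "patient_id": pid,
                        "compartment": comp,
                        "batch": batches[i % len(batches)],
                    }
                )
                i += 1
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class Circ:
    junction_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    stratum: str


@dataclass
class SimTruth:
    true_candidates: list[str] = field(default_factory=list)
    exclusion_ids: list[str] = field(default_factory=list)
    planted_sites: list[tuple[str, str]] = field(default_factory=list)
    planted_mirna_targets: list[tuple[str, str]] = field(default_factory=list)
    partner_gene: dict = field(default_factory=dict)  # circ -> coexpressed gene
    group_assignment: dict = field(default_factory=dict)
    per_patient_burden: dict = field(default_factory=dict)
    true_hr: float = 1.0
    ctdna_rho: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)
            fh.write("\n")


def generate_gene_models(config: CohortConfig, rng=None):
    """Toy genome (random sequence over a few chromosomes) plus multi-exon
    gene models placed end to end with intergenic gaps."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genome = {
        chrom: "".join(rng.choice(BASES, size=length))
        for chrom, length in config.chrom_lengths
    }
    chroms = [c for c, _ in config.chrom_lengths]
    lengths = dict(config.chrom_lengths)
    cursor = {c: 1000 for c in chroms}
    models = []
    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        n_exons = int(rng.integers(3, 8))
        exon_lens = rng.integers(80, 301, size=n_exons)
        intron_lens = rng.integers(100, 401, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        start = cursor[chrom]
        if start + span > lengths[chrom] - 1000:
            raise InvalidConfigError(
                "toy genome too small for requested gene count"
            )
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        cursor[chrom] = pos + int(rng.integers(500, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            GeneModel(f"G{gi + 1:04d}", chrom, start, exons[-1][1], strand,
                      tuple(exons))
        )
    return models, genome


def simulate_circ_truth(config: CohortConfig, gene_models, rng):
    """Draw circRNAs as exon-boundary pairs and assign screening strata."""
    config.validate()
    seen = set()
    circs: list[Circ] = []
    strata = (
        [CANDIDATE] * config.n_candidates_true
        + [BRAIN_LISTED] * config.n_brain_listed
    )
    n_rest = config.n_circ_total - len(strata)
    strata += [CSF_NONRECURRENT] * (n_rest // 2)
    strata += [NON_CSF] * (n_rest - n_rest // 2)
    attempts = 0
    while len(circs) < config.n_circ_total:
        attempts += 1
        if attempts > 50 * config.n_circ_total:
            raise InvalidConfigError("cannot draw enough distinct circRNAs")
        g = gene_models[int(rng.integers(len(gene_models)))]
        i = int(rng.integers(len(g.exons)))
        j = int(rng.integers(i, len(g.exons)))
        start, end = g.exons[i][0], g.exons[j][1]
        jid = format_junction_id(g.chrom, start, end, g.strand)
        if jid in seen:
            continue
        seen.add(jid)
        circs.append(
            Circ(jid, g.chrom, start, end, g.strand, g.gene_id,
                 strata[len(circs)])
        )
    truth = SimTruth(
        true_candidates=sorted(c.junction_id for c in circs
                               if c.stratum == CANDIDATE),
        exclusion_ids=sorted(c.junction_id for c in circs
                             if c.stratum == BRAIN_LISTED),
        true_hr=config.hazard_ratio_abundant,
        ctdna_rho=config.ctdna_rho,
    )
    return circs, truth


def _nb_counts(rng, mean, dispersion, size=None):
    """Negative-binomial counts with mean ``mean`` and dispersion 1/size_nb."""
    size_nb = 1.0 / dispersion
    p = size_nb / (size_nb + np.asarray(mean, float))
    return rng.negative_binomial(size_nb, p, size=size)


def simulate_expression(config: CohortConfig, circs, gene_models, truth, rng):
    """Per-sample circRNA and linear-gene count matrices.

    CSF detection follows per-circ, per-patient Bernoulli masks (the
    heterogeneity mechanism): non-candidate CSF-capable species are kept
    with probability ``csf_species_fraction``, and CSF means are boosted
    by ``csf_abundance_factor``. Candidate detection is driven by the
    patient's latent group (abundant vs deficient), which later drives the
    survival hazard. Each candidate gets a co-expressed partner gene whose
    log-expression tracks the candidate's with correlation ``coexpr_rho``.
    """
    samples = config.sample_sheet()
    sample_ids = list(samples.index)
    csf_patients = sorted(samples[samples["compartment"] == "csf"]["patient_id"])
    tissue_patients = sorted(samples[samples["compartment"] == "tissue"]["patient_id"])

    n_abundant = max(1, round(config.abundant_fraction * len(csf_patients)))
    abundant = sorted(
        rng.choice(csf_patients, size=n_abundant, replace=False).tolist()
    )
    truth.group_assignment = {
        p: ("abundant" if p in abundant else "deficient") for p in csf_patients
    }

    base_mean = np.exp(
        rng.normal(np.log(config.mean_circ_count), 0.8, size=len(circs))
    )

    # presence masks, then NB counts on top
    counts = pd.DataFrame(
        0, index=[c.junction_id for c in circs], columns=sample_ids, dtype=int
    )
    for ci, circ in enumerate(circs):
        mu = base_mean[ci]
        # tissue presence by stratum
        if circ.stratum == CANDIDATE:
            k = int(rng.integers(2, min(5, len(tissue_patients)) + 1))
            tissue_set = set(
                rng.choice(tissue_patients, size=k, replace=False).tolist()
            )
        elif circ.stratum == CSF_NONRECURRENT:
            tissue_set = set(
                rng.choice(tissue_patients, size=int(rng.integers(0, 2)),
                           replace=False).tolist()
            )
        else:
            tissue_set = {
                p for p in tissue_patients if rng.random() < 0.5
            }
        for sid in sample_ids:
            comp = samples.loc[sid, "compartment"]
            pid = samples.loc[sid, "patient_id"]
            present = False
            factor = 1.0
            if comp == "tissue":
                present = pid in tissue_set
                disp = config.dispersion_tissue
            elif comp == "plasma":
                present = rng.random() < 0.6
                disp = config.dispersion
            else:  # csf
                disp = config.dispersion
                factor = config.csf_abundance_factor
                if circ.stratum == CANDIDATE:
                    p_det = 0.8 if truth.group_assignment[pid] == "abundant" else 0.15
                    present = rng.random() < p_det
                elif circ.stratum in (BRAIN_LISTED, CSF_NONRECURRENT):
                    present = rng.random() < config.csf_species_fraction
                else:
                    present = False
            if present:
                counts.loc[circ.junction_id, sid] = 1 + int(
                    _nb_counts(rng, mu * factor, disp)
                )
        if circ.stratum == CANDIDATE:
            csf_cols = [f"{p}_csf" for p in csf_patients]
            if not counts.loc[circ.junction_id, csf_cols].gt(0).any():
                sid = f"{abundant[0]}_csf"
                counts.loc[circ.junction_id, sid] = 1 + int(
                    _nb_counts(rng, mu * config.csf_abundance_factor,
                               config.dispersion)
                )

    # linear genes: baseline NB everywhere; candidate partner genes coupled
    gene_ids = [g.gene_id for g in gene_models]
    gene_mean = np.exp(
        rng.normal(np.log(config.mean_gene_count), 0.7, size=len(gene_ids))
    )
    linear = pd.DataFrame(
        _nb_counts(
            rng,
            np.outer(gene_mean, np.ones(len(sample_ids))),
            config.dispersion,
        ),
        index=gene_ids,
        columns=sample_ids,
    )

    parent_genes = {c.gene_id for c in circs}
    free_genes = [g for g in gene_ids if g not in parent_genes]
    candidates = [c for c in circs if c.stratum == CANDIDATE]
    for k, circ in enumerate(candidates):
        partner = (free_genes[k % len(free_genes)] if free_genes
                   else gene_ids[k % len(gene_ids)])
        truth.partner_gene[circ.junction_id] = partner
        linear.loc[partner] = coupled_counts(
            counts.loc[circ.junction_id].to_numpy(float),
            mean=gene_mean[gene_ids.index(partner)],
            rho=config.coexpr_rho,
            rng=rng,
        )
    return counts, linear


def coupled_counts(circ_counts: np.ndarray, mean: float, rho: float, rng):
    """Partner-gene counts whose log-expression tracks a circRNA profile.

    The partner's log-mean is rho * z + sqrt(1-rho^2) * eps, where z is the
    standardized log circRNA count, so the planted log-scale correlation
    is ``rho``; counts are drawn NB with low dispersion around that mean.
    """
    z = np.log2(circ_counts + 1.0)
    sd = z.std()
    z = (z - z.mean()) / (sd if sd > 0 else 1.0)
    eps = rng.normal(size=circ_counts.size)
    latent = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps
    mu = mean * np.exp(1.2 * latent)
    return 1 + _nb_counts(rng, mu, 0.01)


def simulate_chimeric_records(
    config: CohortConfig, circs, counts: pd.DataFrame, rng, outdir=None,
    decoys: bool = True,
):
    """Back-splice chimeric records per sample: one record per supporting read.

    A circ with count k in a sample yields exactly k records whose donor /
    acceptor coordinates reconstruct the junction, with both anchors at
    least ``anchor_size``. Decoy chimeras (inter-chromosomal and
    linear-order) are appended when ``decoys`` is true; none of them
    satisfies the back-splice geometry.
    """
    by_id = {c.junction_id: c for c in circs}
    files = {}
    for sid in counts.columns:
        lines = []
        ridx = 0
        for jid, k in counts[sid].items():
            if k == 0:
                continue
            c = by_id[jid]
            for _ in range(int(k)):
                ridx += 1
                anchor_a = int(
                    rng.integers(config.anchor_size,
                                 config.read_length - config.anchor_size + 1)
                )
                anchor_b = config.read_length - anchor_a
                if c.strand == "+":
                    pos_a, pos_b = c.end + 1, c.start
                else:
                    pos_a, pos_b = c.start, c.end + 1
                lines.append(
                    f"{c.chrom}\t{pos_a}\t{c.strand}\t{c.chrom}\t{pos_b}\t"
                    f"{c.strand}\t1\t{anchor_a}\t{anchor_b}\t{sid}_r{ridx}"
                )
        if decoys:
            chroms = [ch for ch, _ in config.chrom_lengths]
            for d in range(config.decoys_per_sample):
                ridx += 1
                strand = "+" if rng.random() < 0.5 else "-"
                if d % 2 == 0:  # inter-chromosomal fusion-like chimera
                    ca, cb = rng.choice(chroms, size=2, replace=False)
                    pa = int(rng.integers(1000, 200_000))
                    pb = int(rng.integers(1000, 200_000))
                else:  # same-chrom linear-order chimera (normal splice side)
                    ca = cb = chroms[int(rng.integers(len(chroms)))]
                    pa = int(rng.integers(1000, 100_000))
                    gap = int(rng.integers(1000, 50_000))
                    pb = pa + gap if strand == "+" else pa - gap
                    if pb < 1:
                        pb = pa + gap
                        pa, pb = pb, pa  # keep linear order on '-'
                lines.append(
                    f"{ca}\t{pa}\t{strand}\t{cb}\t{pb}\t{strand}\t-1\t"
                    f"{config.anchor_size}\t{config.anchor_size}\t{sid}_d{ridx}"
                )
        text = "\n".join(lines) + ("\n" if lines else "")
        files[sid] = text
        if outdir is not None:
            path = Path(outdir) / f"{sid}.chimeric.tsv"
            path.write_text(text)
    return files


def simulate_mirnas(config: CohortConfig, circs, gene_models, genome, truth, rng):
    """miRNA and 3'UTR FASTA content with planted junction-spanning sites.

    Each candidate circ gets one miRNA exactly complementary to a 22-nt
    window centred on its junction probe's back-splice joint (so the site
    cannot occur on the linear transcript), plus random decoy miRNAs; the
    partner gene's 3'UTR carries an exact 8mer seed site for that miRNA.
    """
    genes_by_id = {g.gene_id: g for g in gene_models}
    mirnas: dict[str, str] = {}
    utrs: dict[str, str] = {}
    candidates = [c for c in circs if c.stratum == CANDIDATE]
    for k, c in enumerate(candidates, start=1):
        gene = genes_by_id[c.gene_id]
        seq = sponge.spliced_circ_sequence(
            c.junction_id, c.chrom, c.start, c.end, c.strand, gene, genome
        )
        probe = sponge.build_probe(c.junction_id, seq, config.flank_nt)
        off = probe.junction_offset
        j0 = max(0, min(off - 11, len(probe.sequence) - 22))
        window = probe.sequence[j0:j0 + 22]
        mid = f"sim-miR-{k:03d}"
        mirnas[mid] = sponge.revcomp_rna(window)
        truth.planted_sites.append((c.junction_id, mid))
    for d in range(1, config.n_mirna_decoys + 1):
        mirnas[f"sim-miR-decoy-{d:03d}"] = "".join(
            rng.choice(np.array(list("ACGU")), size=22)
        )
    # 3'UTRs: random backbone; partner genes get an exact 8mer site
    for g in gene_models:
        utrs[g.gene_id] = "".join(rng.choice(BASES, size=config.utr_length))
    for (circ_id, mid) in truth.planted_sites:
        partner = truth.partner_gene.get(circ_id)
        if partner is None:
            continue
        site = sponge.seed_site(mirnas[mid]) + "A"
        site_dna = site.replace("U", "T")
        utr = utrs[partner]
        pos = int(rng.integers(10, config.utr_length - len(site_dna) - 10))
        utrs[partner] = utr[:pos] + site_dna + utr[pos + len(site_dna):]
        truth.planted_mirna_targets.append((mid, partner))
    return mirnas, utrs


def simulate_clinical(config: CohortConfig, truth, burden: dict, csf_abundance: dict, rng):
    """Clinical table with group-dependent survival and ctDNA values.

    OS times are exponential with baseline rate log(2)/median_os,
    multiplied by the configured hazard ratio for circRNA-abundant
    patients; censoring is uniform on [0, max_followup]. ctDNA is drawn so
    its correlation with CSF circRNA abundance targets ``ctdna_rho``.
    """
    config.validate()
    lam0 = np.log(2.0) / config.median_os_months
    rows = []
    csf_pats = sorted(csf_abundance)
    abun = np.array([csf_abundance[p] for p in csf_pats], float)
    z = np.log2(abun + 1.0)
    sd = z.std()
    z = (z - z.mean()) / (sd if sd > 0 else 1.0)
    eps = rng.normal(size=len(csf_pats))
    rho = config.ctdna_rho
    ctdna_z = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps
    ctdna = dict(zip(csf_pats, 10.0 + 3.0 * ctdna_z))
    for pid in config.patient_ids:
        group = truth.group_assignment.get(pid, "deficient")
        hr = config.hazard_ratio_abundant if group == "abundant" else 1.0
        t_event = rng.exponential(1.0 / (lam0 * hr))
        t_cens = rng.uniform(0.0, config.max_followup_months)
        os_months = min(t_event, t_cens)
        rows.append(
            {
                "patient_id": pid,
                "os_months": round(float(os_months), 3),
                "event": int(t_event <= t_cens),
                "age": int(np.clip(round(rng.normal(55, 8)), 39, 74)),
                "sex": int(rng.random() < 9 / 21),  # 1 = male
                "smoking": int(rng.random() < 6 / 21),
                "metastasis": int(rng.random() < 18 / 21),
                "ctdna": round(float(ctdna.get(pid, np.nan)), 3)
                if pid in ctdna else np.nan,
                "group": group,
                "burden": burden.get(pid, np.nan),
            }
        )
    truth.per_patient_burden = dict(burden)
    return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    config: CohortConfig
    gene_models: list
    genome: dict
    circs: list
    truth: SimTruth
    samples: pd.DataFrame
    circ_counts: pd.DataFrame
    linear_counts: pd.DataFrame
    chimeric: dict
    mirnas: dict
    utrs: dict
    clinical: pd.DataFrame


def simulate_cohort(config: CohortConfig, outdir=None, decoys: bool = True) -> SimulatedCohort:
    """Run the full generator; optionally write all artifacts to ``outdir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_models, genome = generate_gene_models(config, rng)
    circs, truth = simulate_circ_truth(config, gene_models, rng)
    circ_counts, linear_counts = simulate_expression(
        config, circs, gene_models, truth, rng
    )
    samples = config.sample_sheet()
    chimeric = simulate_chimeric_records(
        config, circs, circ_counts, rng,
        outdir=None if outdir is None else _ensure(Path(outdir) / "chimeric"),
        decoys=decoys,
    )
    mirnas, utrs = simulate_mirnas(config, circs, gene_models, genome, truth, rng)
    csf_samples = samples.index[samples["compartment"] == "csf"]
    det = circ_counts.reindex(truth.true_candidates)[csf_samples].gt(0)
    burden = {
        samples.loc[sid, "patient_id"]: int(det[sid].sum())
        for sid in csf_samples
    }
    csf_abundance = {
        samples.loc[sid, "patient_id"]: float(circ_counts[sid].sum())
        for sid in csf_samples
    }
    clinical = simulate_clinical(config, truth, burden, csf_abundance, rng)
    cohort = SimulatedCohort(
        config=config, gene_models=gene_models, genome=genome, circs=circs,
        truth=truth, samples=samples, circ_counts=circ_counts,
        linear_counts=linear_counts, chimeric=chimeric, mirnas=mirnas,
        utrs=utrs, clinical=clinical,
    )
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def _ensure(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    out = _ensure(Path(outdir))
    write_fasta(cohort.genome, out / "genome.fa")
    write_bed12(cohort.gene_models, out / "genes.bed")
    write_fasta(cohort.mirnas, out / "mirnas.fa")
    write_fasta(
        {g: s.replace("U", "T") for g, s in cohort.utrs.items()},
        out / "utrs.fa",
    )
    cohort.circ_counts.rename_axis("feature_id").to_csv(
        out / "circ_counts.tsv", sep="\t"
    )
    cohort.linear_counts.rename_axis("feature_id").to_csv(
        out / "linear_counts.tsv", sep="\t"
    )
    with open(out / "exclusion.tsv", "w") as fh:
        for jid in cohort.truth.exclusion_ids:
            fh.write(jid + "\n")
    cohort.samples.to_csv(out / "samples.csv")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.truth.to_json(out / "truth.json")
    chim_dir = _ensure(out / "chimeric")
    for sid, text in cohort.chimeric.items():
        (chim_dir / f"{sid}.chimeric.tsv").write_text(text)
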