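"""circRNA-miRNA-mRNA sponge-network construction.

A circRNA can act as a miRNA sponge; binding sites that span the
back-splice joint are unique to the circular form, so miRNA binding is
scored against a *junction probe*: the last ``flank_nt`` nucleotides of
the spliced circle joined to its first ``flank_nt`` ("reverse-joined"),
recreating the joint in linear sequence space.

The duplex scorer is a miRanda-style local alignment of the miRNA (3'->5')
against the probe (5'->3'): Watson-Crick pairs +5, G:U wobble +1,
mismatches -3, affine gaps (-9 open, -4 extend), with pair scores at
miRNA seed positions 2-8 weighted x4. The duplex energy is a per-pair sum
(G:C -3.0, A:U -2.0, G:U -1.0 kcal/mol) over aligned pairs — a fast
surrogate for a nearest-neighbor thermodynamic model. A hit requires
score > score_min AND energy < energy_max; strict mode additionally
requires the whole seed (positions 2-8) to be Watson-Crick paired and
ungapped.

miRNA->mRNA edges use canonical seed matching in the 3'UTR (7mer-m8, with
the 8mer subclass when an A faces miRNA position 1); circRNA->mRNA
co-expression edges require |Pearson r| >= 0.70 and p < 0.01.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError
from .profiling import pearson_with_p

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
DNA_TO_RNA = str.maketrans("Tt", "Uu")

MATCH_WC = 5.0
MATCH_WOBBLE = 1.0
MISMATCH = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
SEED_WEIGHT = 4.0
SEED_RANGE = (2, 8)  # miRNA positions, 1-based inclusive
ENERGY_GC = -3.0
ENERGY_AU = -2.0
ENERGY_GU = -1.0


def to_rna(seq: str) -> str:
    seq = seq.upper().translate(DNA_TO_RNA)
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    return seq


def revcomp_rna(seq: str) -> str:
    return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))


def is_wc(a: str, b: str) -> bool:
    return RNA_COMPLEMENT[a] == b


def is_wobble(a: str, b: str) -> bool:
    return (a, b) in (("G", "U"), ("U", "G"))


def pair_energy(a: str, b: str) -> float:
    if is_wc(a, b):
        return ENERGY_GC if a in "GC" else ENERGY_AU
    if is_wobble(a, b):
        return ENERGY_GU
    return 0.0


@dataclass(frozen=True)
class JunctionProbe:
    circ_id: str
    sequence: str  # RNA alphabet
    junction_offset: int  # joint sits between offset-1 and offset


@dataclass
class DuplexHit:
    mirna_id: str
    circ_id: str
    score: float
    energy: float
    alignment: tuple  # ((mirna_pos_1based, probe_pos_0based), ...)
    spans_junction: bool
    strict_seed: bool


def spliced_circ_sequence(junction_id, chrom, start, end, strand, gene, genome) -> str:
    """Assemble the mature (spliced) circRNA sequence from its gene model.

    Exons of the parental gene falling inside [start, end) are
    concatenated; the junction ends must coincide with exon boundaries.
    Minus-strand circles are reverse-complemented so the sequence reads
    5'->3' on the transcript.
    """
    if start not in gene.exon_starts or end not in gene.exon_ends:
        raise ValueError(
            f"{junction_id}: junction ends do not match exon boundaries of {gene.gene_id}"
        )
    parts = [
        genome[chrom][s:e] for s, e in gene.exons if s >= start and e <= end
    ]
    seq = to_rna("".join(parts))
    if strand == "-":
        seq = revcomp_rna(seq)
    return seq


def build_probe(circ_id, circ_seq: str, flank_nt: int = 30) -> JunctionProbe:
    """Reverse-join the circle's 3' and 5' flanks across the back-splice joint.

    For circles shorter than 2*flank_nt the flanks shrink to floor(L/2)
    tail + remaining head, so the probe is the full circle exactly once.
    """
    seq = to_rna(circ_seq)
    length = len(seq)
    if length >= 2 * flank_nt:
        tail_len = head_len = flank_nt
    else:
        tail_len = length // 2
        head_len = length - tail_len
    probe = seq[length - tail_len:] + seq[:head_len]
    return JunctionProbe(circ_id, probe, junction_offset=tail_len)


def _local_duplex_align(mirna: str, probe: str):
    """Gotoh local alignment of the reversed miRNA against the probe.

    Returns (score, pairs) where pairs are (mirna_pos_1based, probe_pos)
    aligned pairs along the optimal local alignment.
    """
    rev = mirna[::-1]  # rev[i] is miRNA position m - i (1-based)
    m, n = len(rev), len(probe)

    def weight(i):  # i: 0-based index into rev
        pos = m - i  # original 1-based miRNA position
        return SEED_WEIGHT if SEED_RANGE[0] <= pos <= SEED_RANGE[1] else 1.0

    def pscore(i, j):
        a, b = rev[i], probe[j]
        if is_wc(a, b):
            base = MATCH_WC
        elif is_wobble(a, b):
            base = MATCH_WOBBLE
        else:
            base = MISMATCH
        return base * weight(i)

    NEG = -1e18
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in rev (consumes probe)
    F = np.full((m + 1, n + 1), NEG)  # gap in probe (consumes rev)
    ptr = {}
    best, best_cell = 0.0, None
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND)
            diag = H[i - 1][j - 1] + pscore(i - 1, j - 1)
            h = max(0.0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h == 0:
                ptr[(i, j)] = None
            elif h == diag:
                ptr[(i, j)] = ("M", i - 1, j - 1)
            elif h == E[i][j]:
                ptr[(i, j)] = ("E", i, j - 1)
            else:
                ptr[(i, j)] = ("F", i - 1, j)
            if h > best:
                best, best_cell = h, (i, j)
    pairs = []
    cell = best_cell
    # traceback through H; E/F runs are unwound greedily
    while cell is not None and H[cell[0]][cell[1]] > 0:
        step = ptr.get(cell)
        if step is None:
            break
        kind, pi, pj = step
        if kind == "M":
            i, j = cell
            pairs.append((m - (i - 1), j - 1))  # miRNA 1-based pos, probe 0-based
            cell = (pi, pj)
        elif kind == "E":
            i, j = cell
            jj = j
            while jj > 0 and E[i][jj] == E[i][jj - 1] + GAP_EXTEND and H[i][jj - 1] + GAP_OPEN < E[i][jj - 1] + GAP_EXTEND:
                jj -= 1
            cell = (i, jj - 1)
        else:
            i, j = cell
            ii = i
            while ii > 0 and F[ii][j] == F[ii - 1][j] + GAP_EXTEND and H[ii - 1][j] + GAP_OPEN < F[ii - 1][j] + GAP_EXTEND:
                ii -= 1
            cell = (ii - 1, j)
    pairs.reverse()
    return best, tuple(pairs)


def duplex_score(
    mirna_seq: str,
    probe: JunctionProbe,
    mirna_id: str = "mirna",
    score_min: float = 170.0,
    energy_max: float = -30.0,
    strict: bool = True,
) -> DuplexHit | None:
    """Score a miRNA against a junction probe; return a hit or None.

    A hit requires score > score_min and energy < energy_max; in strict
    mode the seed (miRNA positions 2-8) must additionally be fully
    Watson-Crick paired without gaps.
    """
    mirna = to_rna(mirna_seq)
    if not mirna or not probe.sequence:
        raise ValueError("empty sequence")
    score, pairs = _local_duplex_align(mirna, probe.sequence)
    if not pairs:
        return None
    energy = sum(pair_energy(mirna[p - 1], probe.sequence[j]) for p, j in pairs)
    strict_ok = _strict_seed_ok(mirna, probe.sequence, pairs)
    probe_js = [j for _, j in pairs]
    spans = min(probe_js) < probe.junction_offset <= max(probe_js)
    if score <= score_min or energy >= energy_max:
        return None
    if strict and not strict_ok:
        return None
    return DuplexHit(
        mirna_id=mirna_id,
        circ_id=probe.circ_id,
        score=score,
        energy=energy,
        alignment=pairs,
        spans_junction=spans,
        strict_seed=strict_ok,
    )


def _strict_seed_ok(mirna: str, probe: str, pairs) -> bool:
    """Seed positions 2-8 all aligned, Watson-Crick, and gap-free."""
    lo, hi = SEED_RANGE
    by_pos = {p: j for p, j in pairs}
    if not all(p in by_pos for p in range(lo, hi + 1)):
        return False
    for p in range(lo, hi + 1):
        if not is_wc(mirna[p - 1], probe[by_pos[p]]):
            return False
    # antiparallel: probe index must step by exactly -1 as miRNA pos grows
    for p in range(lo, hi):
        if by_pos[p] - by_pos[p + 1] != 1:
            return False
    return True


def predict_circ_mirna(
    probes,
    mirnas: dict[str, str],
    score_min: float = 170.0,
    energy_max: float = -30.0,
    strict: bool = True,
) -> list[DuplexHit]:
    """Score every (probe, miRNA) pair; filtered hits sorted by circ then score."""
    if not mirnas:
        raise ValueError("empty miRNA set")
    hits = []
    for probe in probes:
        for mid, seq in mirnas.items():
            hit = duplex_score(
                seq, probe, mirna_id=mid, score_min=score_min,
                energy_max=energy_max, strict=strict,
            )
            if hit is not None:
                hits.append(hit)
    hits.sort(key=lambda h: (h.circ_id, -h.score, h.mirna_id))
    return hits


def seed_site(mirna_seq: str) -> str:
    """Reverse complement of miRNA positions 2-8: the 7mer-m8 site."""
    mirna = to_rna(mirna_seq)
    if len(mirna) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    return revcomp_rna(mirna[1:8])


def predict_mirna_mrna(
    mirnas: dict[str, str], utrs: dict[str, str]
) -> pd.DataFrame:
    """Seed-match miRNA->mRNA edges (7mer-m8; 8mer when position-1 A present).

    Returns one row per (miRNA, mRNA) pair with the best match class and
    the number of sites."""
    rows = []
    for mid, mseq in mirnas.items():
        site7 = seed_site(mseq)
        for gene, utr in utrs.items():
            utr_rna = to_rna(utr)
            n_sites = 0
            best = None
            start = utr_rna.find(site7)
            while start != -1:
                n_sites += 1
                after = start + len(site7)
                klass = (
                    "8mer" if after < len(utr_rna) and utr_rna[after] == "A"
                    else "7mer-m8"
                )
                if best is None or klass == "8mer":
                    best = klass
                start = utr_rna.find(site7, start + 1)
            if n_sites:
                rows.append(
                    {
                        "mirna_id": mid,
                        "gene_id": gene,
                        "match_class": best,
                        "n_sites": n_sites,
                    }
                )
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "match_class", "n_sites"])


def coexpression_edges(
    circ_fpkm: pd.DataFrame,
    mrna_fpkm: pd.DataFrame,
    r_min: float = 0.70,
    p_max: float = 0.01,
    transform: str = "log2",
    pairs=None,
) -> pd.DataFrame:
    """circRNA-mRNA co-expression edges: |r| >= r_min (inclusive) and p < p_max.

    Pearson correlation is computed on log2(FPKM + 1) by default
    (``transform="linear"`` uses raw FPKM) over samples shared by the two
    matrices where both features are measured; pairs with fewer than 3
    shared samples are skipped with a warning. ``pairs`` restricts scoring
    to an iterable of (circ_id, gene_id); by default all pairs are scored.
    BH q-values over the scored pairs are reported alongside raw p but not
    used for filtering.
    """
    shared = circ_fpkm.columns.intersection(mrna_fpkm.columns)
    if pairs is None:
        pairs = itertools.product(circ_fpkm.index, mrna_fpkm.index)
    rows = []
    for circ, gene in pairs:
        if circ not in circ_fpkm.index or gene not in mrna_fpkm.index:
            continue
        x = circ_fpkm.loc[circ, shared].astype(float)
        y = mrna_fpkm.loc[gene, shared].astype(float)
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            warnings.warn(f"skipping {circ}~{gene}: <3 shared samples")
            continue
        xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
        if transform == "log2":
            xv, yv = np.log2(xv + 1.0), np.log2(yv + 1.0)
        try:
            r, p = pearson_with_p(xv, yv)
        except DegenerateDataError:
            continue
        rows.append({"circ_id": circ, "gene_id": gene, "n": int(ok.sum()),
                     "r": r, "p_value": p})
    table = pd.DataFrame(rows, columns=["circ_id", "gene_id", "n", "r", "p_value"])
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["edge"] = (table["r"].abs() >= r_min) & (table["p_value"] < p_max)
    else:
        table["q_value"] = []
        table["edge"] = []
    return table


def assemble_network(
    circ_mirna_hits,
    mirna_mrna_edges: pd.DataFrame,
    coexpr_edges: pd.DataFrame | None = None,
    keep_isolated: bool = False,
    extra_nodes: dict | None = None,
):
    """Assemble the tripartite network as (nodes, edges) DataFrames.

    Node IDs must be unique across the circRNA / miRNA / mRNA classes.
    Only edges present in the inputs appear; co-expression rows are taken
    only where their ``edge`` flag is true. Isolated nodes (from
    ``extra_nodes``: id -> kind) are dropped unless keep_isolated.
    """
    edges = []
    kinds: dict[str, str] = {}

    def register(node, kind):
        if kinds.get(node, kind) != kind:
            raise ValueError(f"node ID {node!r} used for both "
                             f"{kinds[node]} and {kind}")
        kinds[node] = kind

    for h in circ_mirna_hits:
        register(h.circ_id, "circRNA")
        register(h.mirna_id, "miRNA")
        edges.append(
            {"source": h.circ_id, "target": h.mirna_id,
             "edge_type": "circ-mirna", "score": h.score, "energy": h.energy}
        )
    for _, row in mirna_mrna_edges.iterrows():
        register(row["mirna_id"], "miRNA")
        register(row["gene_id"], "mRNA")
        edges.append(
            {"source": row["mirna_id"], "target": row["gene_id"],
             "edge_type": "mirna-mrna", "match_class": row["match_class"]}
        )
    if coexpr_edges is not None and len(coexpr_edges):
        for _, row in coexpr_edges[coexpr_edges["edge"]].iterrows():
            register(row["circ_id"], "circRNA")
            register(row["gene_id"], "mRNA")
            edges.append(
                {"source": row["circ_id"], "target": row["gene_id"],
                 "edge_type": "circ-mrna-coexpr", "r": row["r"],
                 "p_value": row["p_value"]}
            )
    if keep_isolated and extra_nodes:
        for node, kind in extra_nodes.items():
            register(node, kind)
    edge_df = pd.DataFrame(
        edges, columns=["source", "target", "edge_type", "score", "energy",
                        "match_class", "r", "p_value"]
    )
    connected = set(edge_df["source"]) | set(edge_df["target"])
    node_rows = [
        {"node_id": n, "kind": k}
        for n, k in sorted(kinds.items())
        if keep_isolated or n in connected
    ]
    node_df = pd.DataFrame(node_rows, columns=["node_id", "kind"])
    return node_df, edge_df


def to_networkx(node_df: pd.DataFrame, edge_df: pd.DataFrame):
    import networkx as nx

    g = nx.Graph()
    for _, row in node_df.iterrows():
        g.add_node(row["node_id"], kind=row["kind"])
    for _, row in edge_df.iterrows():
        attrs = {k: v for k, v in row.items()
                 if k not in ("source", "target") and pd.notna(v)}
        g.add_edge(row["source"], row["target"], **attrs)
    return g


def hypergeom_enrichment(
    gene_list, gene_sets: dict[str, set], universe
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each gene set.

    Upper-tail hypergeometric p per set (drawing n = |list| genes from the
    universe, K = |set ∩ universe| of which are in the set, observing k
    overlaps); BH q-values reported alongside."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_list) & universe
    if set(gene_list) - universe:
        raise ValueError("gene list must be a subset of the universe")
    M, n = len(universe), len(genes)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(genes & members)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        expected = n * K / M if M else 0.0
        rows.append(
            {"gene_set": name, "n_overlap": k, "set_size": K,
             "fold_enrichment": (k / expected) if expected else np.nan,
             "p_value": min(p, 1.0)}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table
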