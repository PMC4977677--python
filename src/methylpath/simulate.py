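"""Self-contained synthetic multi-genotype datasets with known ground truth.

The generator plants, per TE: a methylation pathway category in each
background (encoded as the epistasis pattern of mean CHH methylation across
mutant genotypes), a length class relative to a family consensus (with the
matching consensus-coverage intervals and domain content), transcriptional
competence, and cleavage sites with known RDR6 dependence. Everything the
pipeline consumes — genome FASTA, GFF3 annotations, per-genotype cytosine
tables, sRNA count tables, PARE tables, hit/coverage/landmark tables and run
configs — is emitted in the formats the io module reads, alongside a truth
table, so recovery of the planted labels is measurable end to end.

Per-cytosine counts are n_total ~ Poisson(depth), n_meth ~ Binomial(n_total,
p) where p depends on genomic context, TE membership and the genotype role
according to the planted category. No read-level artefacts (bisulfite
non-conversion, mapping bias) are modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as mio
from .io import Feature, GenotypeManifest, PipelineConfig
from .te_structure import ConsensusCoverage, ESSENTIAL_DOMAINS, landmark_fraction

#: synthetic TE families: name -> (superfamily, consensus length bp)
FAMILIES = {
    "AthilaSim": ("LTR/Gypsy", 2600),
    "CopiaSim": ("LTR/Copia", 1800),
    "LineSim": ("LINE/L1", 1100),
    "MuSim": ("DNA/MuDR", 700),
}

SILENT_CATEGORY_PROPS = {
    "NO_CHH": 0.15, "POLIV_RDDM": 0.40, "RDR6_RDDM": 0.06, "DCL3_RDDM": 0.06,
    "COREGULATED": 0.13, "MAINTENANCE": 0.20,
}
ACTIVE_CATEGORY_PROPS = {
    "NO_CHH": 0.10, "POLIV_RDDM": 0.30, "RDR6_RDDM": 0.22, "DCL3_RDDM": 0.10,
    "COREGULATED": 0.13, "MAINTENANCE": 0.15,
}
LENGTH_CLASS_PROPS = {"FULL_LENGTH": 0.30, "INTERMEDIATE": 0.30, "FRAGMENT": 0.40}

#: which canonical mutant roles lose CHH methylation for each planted category
AFFECTED_ROLES = {
    "POLIV_RDDM": ("polIV", "rdr2", "polV", "polIV_rdr6"),
    "RDR6_RDDM": ("rdr6", "polV", "polIV_rdr6"),
    "DCL3_RDDM": ("dcl3", "polV"),
    "COREGULATED": ("polIV_rdr6", "polV"),
    "MAINTENANCE": (),
    "NO_CHH": (),
}


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the package's standard study
    conditions (500 TEs, ~200 CHH cytosines per TE, Poisson(20) coverage,
    4-fold methylation loss in affected mutants)."""

    seed: int = 0
    n_te: int = 500
    n_genes: int = 40
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 340_000,
                                                       "chr2": 340_000})
    # methylation means
    chh_high: float = 0.15
    chg_high: float = 0.45
    cg_high: float = 0.85
    effect_factor: float = 4.0
    no_chh_level: float = 0.002
    background_levels: dict = field(default_factory=lambda: {
        "CG": 0.10, "CHG": 0.03, "CHH": 0.005})
    depth_mean: float = 20.0
    # structure
    category_props_silent: dict = field(
        default_factory=lambda: dict(SILENT_CATEGORY_PROPS))
    category_props_active: dict = field(
        default_factory=lambda: dict(ACTIVE_CATEGORY_PROPS))
    length_class_props: dict = field(
        default_factory=lambda: dict(LENGTH_CLASS_PROPS))
    te_mutation_rate: float = 0.02
    n_duplicate_pairs: int = 2        # exact-copy TE pairs (semi-mappable)
    n_buried_duplicate_pairs: int = 1  # exact copies incl. flanks (non-mappable)
    min_gap: int = 80
    # expression / small RNA / cleavage
    srna_library_total: int = 2_000_000
    sirna24_mean: float = 150.0   # raw 23-25 nt reads at a Pol IV/DCL3 target
    sirna2122_mean: float = 300.0  # raw 21-22 nt reads at an active RDR6 target
    srna_noise_mean: float = 0.4
    competent_extra_prob: float = 0.25  # competence among non-RDR6 TEs
    primary_cleaved_prob: float = 0.5   # primary-only cleavage among competent
    rnaseq_rpm_competent: tuple = (2.0, 50.0)
    rnaseq_rpm_incompetent: tuple = (0.0, 0.5)
    true_site_p: tuple = (1e-5, 0.01)
    false_site_p: tuple = (0.05, 1.0)
    n_false_sites: int = 40
    include_extra_roles: bool = True  # also emit rdr2 tables

    def __post_init__(self) -> None:
        if self.effect_factor <= 2.0:
            raise ValueError("effect_factor must exceed the 2-fold loss "
                             "threshold for the truth to be recoverable")
        for props in (self.category_props_silent, self.category_props_active,
                      self.length_class_props):
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError("category/class proportions must sum to 1")


def _domain_intervals(consensus_length: int) -> dict[str, tuple]:
    """Landmark layout of an idealized autonomous element: LTRs at the ends,
    the coding domains in order between them."""
    L = consensus_length
    ltr = max(60, L // 18)
    internal = L - 2 * ltr
    coding = ("GAG", "AP", "RT", "RNaseH", "INT")
    out = {"LTR5": (0, ltr), "LTR3": (L - ltr, L)}
    span = internal // len(coding)
    for i, d in enumerate(coding):
        s = ltr + i * span
        out[d] = (s + span // 8, s + span - span // 8)
    return out


@dataclass
class SyntheticDataset:
    """Everything one simulation produced, in memory."""

    params: SimulationParams
    genome: dict
    consensus: dict
    tes: list
    genes: list
    truth: pd.DataFrame
    truth_cleavage: pd.DataFrame
    coverages: dict
    landmarks: dict            # family -> {landmark -> (start, end)}
    domain_hits: pd.DataFrame  # te_id, domain, covered_fraction
    methylomes: dict           # background -> {role -> calls DataFrame}
    srna_counts: pd.DataFrame  # feature_id, library_id, size, count
    srna_library_totals: dict
    pare: pd.DataFrame
    rnaseq: pd.DataFrame       # feature_id, rpm

    def write(self, outdir) -> Path:
        """Write the full file set (FASTA/GFF3/TSV/YAML) to a directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        with open(out / "consensus.fa", "w") as fh:
            for fam in sorted(self.consensus):
                fh.write(f">{fam}\n{self.consensus[fam]}\n")
        mio.write_features_gff3(self.tes, out / "tes.gff3")
        mio.write_features_gff3(self.genes, out / "genes.gff3")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.truth_cleavage.to_csv(out / "truth_cleavage.tsv", sep="\t",
                                   index=False)
        rows = [(c.te_id, c.consensus_id, c.consensus_length, s, e)
                for c in self.coverages.values() for s, e in c.covered]
        pd.DataFrame(rows, columns=["te_id", "consensus_id", "consensus_length",
                                    "start", "end"]
                     ).to_csv(out / "coverage_intervals.tsv", sep="\t", index=False)
        lrows = [(fam, name, s, e) for fam, marks in sorted(self.landmarks.items())
                 for name, (s, e) in sorted(marks.items())]
        pd.DataFrame(lrows, columns=["family", "landmark", "start", "end"]
                     ).to_csv(out / "landmarks.tsv", sep="\t", index=False)
        self.domain_hits.to_csv(out / "domain_hits.tsv", sep="\t", index=False)
        meth_dir = out / "methylomes"
        meth_dir.mkdir(exist_ok=True)
        for background, tables in self.methylomes.items():
            for role, df in tables.items():
                mio.write_cytosine_table(df, meth_dir / f"{role}.allc.tsv")
            manifest = GenotypeManifest(
                background=background,
                paths={role: f"methylomes/{role}.allc.tsv"
                       for role in tables
                       if role in (mio.SILENT_ROLES if background == "silent"
                                   else mio.ACTIVE_ROLES)})
            mio.write_manifest(manifest, PipelineConfig(),
                               out / f"{background}.cfg.yaml")
        self.srna_counts.to_csv(out / "srna_counts.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(self.srna_library_totals.items()),
                     columns=["library_id", "total_18_28"]
                     ).to_csv(out / "srna_totals.tsv", sep="\t", index=False)
        self.pare.to_csv(out / "pare.tsv", sep="\t", index=False)
        self.rnaseq.to_csv(out / "rnaseq.tsv", sep="\t", index=False)
        return out


def simulate(params: Optional[SimulationParams] = None) -> SyntheticDataset:
    """Run the whole generator; deterministic given ``params.seed``."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    consensus, landmarks = _make_consensus(params, rng)
    truth, coverages, te_seqs, shared_flanks = _plan_tes(params, rng, consensus)
    genome, tes, genes, truth = _assemble_genome(params, rng, truth, te_seqs,
                                                 shared_flanks)
    domain_hits = _domain_hit_table(truth, coverages, landmarks)
    methylomes = {
        "silent": _simulate_methylome(params, rng, genome, tes, truth, "silent"),
        "active": _simulate_methylome(params, rng, genome, tes, truth, "active"),
    }
    truth, truth_cleavage, pare, rnaseq = _plan_expression(params, rng, truth)
    srna_counts, totals = _simulate_srna(params, rng, truth)
    return SyntheticDataset(
        params=params, genome=genome, consensus=consensus, tes=tes,
        genes=genes, truth=truth, truth_cleavage=truth_cleavage,
        coverages=coverages, landmarks=landmarks, domain_hits=domain_hits,
        methylomes=methylomes, srna_counts=srna_counts,
        srna_library_totals=totals, pare=pare, rnaseq=rnaseq)


# ---------------------------------------------------------------------------
# genome and TE structure
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _make_consensus(params, rng):
    consensus = {fam: _random_seq(rng, L) for fam, (_sf, L) in FAMILIES.items()}
    landmarks = {fam: _domain_intervals(len(seq))
                 for fam, seq in consensus.items()}
    return consensus, landmarks


def _draw(rng, props: dict) -> np.ndarray:
    keys = list(props)
    return np.array(keys)[rng.choice(len(keys), size=1, p=list(props.values()))][0]


def _plan_tes(params, rng, consensus):
    """Assign family, length class, categories and consensus coverage per TE;
    derive each copy's sequence from its consensus intervals."""
    rows = []
    coverages: dict[str, ConsensusCoverage] = {}
    te_seqs: dict[str, str] = {}
    fams = list(FAMILIES)
    for i in range(params.n_te):
        te_id = f"TE{i:05d}"
        fam = fams[rng.integers(0, len(fams))]
        L = len(consensus[fam])
        lclass = _draw(rng, params.length_class_props)
        if lclass == "FULL_LENGTH":
            ratio = rng.uniform(0.85, 0.99)
            deletion = L - int(round(ratio * L))
            a = int(rng.integers(L // 4, 3 * L // 4))
            intervals = [(0, a), (a + deletion, L)] if deletion > 0 else [(0, L)]
        elif lclass == "FRAGMENT":
            ratio = rng.uniform(0.04, 0.17)
            flen = max(120, int(round(ratio * L)))
            s = int(rng.integers(0, L - flen))
            intervals = [(s, s + flen)]
        else:
            ratio = rng.uniform(0.30, 0.70)
            tlen = int(round(ratio * L))
            s = int(rng.integers(0, L - tlen))
            intervals = [(s, s + tlen)]
        cov = ConsensusCoverage.from_intervals(te_id, fam, L, intervals)
        seq = "".join(consensus[fam][s:e] for s, e in cov.covered)
        # per-copy divergence from the consensus
        if params.te_mutation_rate > 0:
            arr = np.array(list(seq))
            n_mut = rng.binomial(len(arr), params.te_mutation_rate)
            if n_mut:
                idx = rng.choice(len(arr), size=n_mut, replace=False)
                arr[idx] = _BASES[rng.integers(0, 4, size=n_mut)]
            seq = "".join(arr)
        coverages[te_id] = cov
        te_seqs[te_id] = seq
        rows.append({
            "te_id": te_id, "family": fam, "superfamily": FAMILIES[fam][0],
            "consensus_length": L, "te_length": len(seq),
            "length_class": lclass,
            "category_silent": _draw(rng, params.category_props_silent),
            "category_active": _draw(rng, params.category_props_active),
            "strand": "+" if rng.random() < 0.5 else "-",
        })
    truth = pd.DataFrame(rows)
    # planted exact duplicates: copy the sequence of the partner verbatim.
    # "buried" pairs additionally share both 149 bp flanks so that no
    # read-length window over them is genome-unique (non-mappable class);
    # plain pairs keep unique flanks (semi-mappable class).
    dup_flags = np.full(params.n_te, "", dtype=object)
    shared_flanks: dict[str, tuple[str, str]] = {}
    n_pairs = params.n_duplicate_pairs + params.n_buried_duplicate_pairs
    flank_len = 149  # read length - 1
    # only TEs longer than a read have fully-interior windows, so only they
    # can lose uniqueness from a duplicated body
    eligible = truth.index[truth["te_length"] >= 160].to_numpy()
    if 2 * n_pairs > len(eligible):
        raise ValueError("too many duplicate pairs for n_te")
    picked = rng.choice(eligible, size=2 * n_pairs, replace=False)
    for j in range(n_pairs):
        a, b = int(picked[2 * j]), int(picked[2 * j + 1])
        buried = j >= params.n_duplicate_pairs
        src = truth.loc[a, "te_id"]
        dst = truth.loc[b, "te_id"]
        te_seqs[dst] = te_seqs[src]
        for col in ("family", "superfamily", "consensus_length", "te_length",
                    "length_class", "strand"):
            truth.loc[b, col] = truth.loc[a, col]
        coverages[dst] = ConsensusCoverage(dst, coverages[src].consensus_id,
                                           coverages[src].consensus_length,
                                           coverages[src].covered)
        kind = "buried" if buried else "copy"
        dup_flags[a] = f"{kind}:{dst}"
        dup_flags[b] = f"{kind}:{src}"
        if buried:
            lf, rf = _random_seq(rng, flank_len), _random_seq(rng, flank_len)
            shared_flanks[src] = (lf, rf)
            shared_flanks[dst] = (lf, rf)
    truth["duplicate_of"] = dup_flags
    return truth, coverages, te_seqs, shared_flanks


def _assemble_genome(params, rng, truth: pd.DataFrame, te_seqs: dict,
                     shared_flanks: dict):
    """Place TE blocks without overlap, fill gaps with random sequence, drop
    genes into large gaps. A TE's block is its sequence, wrapped in the shared
    149 bp flanks for buried duplicates."""
    chroms = sorted(params.chrom_sizes)
    order = rng.permutation(len(truth))

    def block_len(i: int) -> int:
        extra = 2 * 149 if truth.loc[i, "te_id"] in shared_flanks else 0
        return int(truth.loc[i, "te_length"]) + extra

    # balance TE load across chromosomes
    assignment: dict[str, list[int]] = {c: [] for c in chroms}
    load = {c: 0 for c in chroms}
    for idx in order:
        c = min(chroms, key=lambda ch: load[ch] / params.chrom_sizes[ch])
        assignment[c].append(int(idx))
        load[c] += block_len(int(idx))

    genome: dict[str, str] = {}
    tes: list[Feature] = []
    starts = np.zeros(len(truth), dtype=int)
    ends = np.zeros(len(truth), dtype=int)
    chrom_of = np.full(len(truth), "", dtype=object)
    for c in chroms:
        size = params.chrom_sizes[c]
        idxs = assignment[c]
        total_te = sum(block_len(i) for i in idxs)
        slack = size - total_te - params.min_gap * (len(idxs) + 1)
        if slack < 0:
            raise ValueError(
                f"infeasible packing: {total_te} bp of TE blocks will not fit "
                f"in {c} ({size} bp) with {params.min_gap} bp gaps")
        raw = rng.random(len(idxs) + 1) ** 4  # heavy tail: a few large gaps
        extras = np.floor(raw / raw.sum() * slack).astype(int)
        parts: list[str] = []
        cursor = 0
        for k, i in enumerate(idxs):
            parts.append(_random_seq(rng, params.min_gap + int(extras[k])))
            cursor += params.min_gap + int(extras[k])
            te_id = truth.loc[i, "te_id"]
            seq = te_seqs[te_id]
            if truth.loc[i, "strand"] == "-":
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            if te_id in shared_flanks:
                lf, rf = shared_flanks[te_id]
                block = lf + seq + rf
                starts[i] = cursor + len(lf)
            else:
                block = seq
                starts[i] = cursor
            ends[i] = starts[i] + len(seq)
            chrom_of[i] = c
            parts.append(block)
            cursor += len(block)
        parts.append(_random_seq(rng, size - cursor))
        genome[c] = "".join(parts)
        for i in idxs:
            row = truth.loc[i]
            tes.append(Feature(id=row.te_id, chrom=c, start=int(starts[i]),
                               end=int(ends[i]), strand=row.strand, kind="TE",
                               family=row.family, superfamily=row.superfamily))
    truth = truth.copy()
    truth["chrom"] = chrom_of
    truth["start"] = starts
    truth["end"] = ends
    tes.sort(key=lambda f: (f.chrom, f.start))
    # genes in the larger inter-TE gaps
    genes: list[Feature] = []
    occupied = {c: sorted([(f.start, f.end) for f in tes if f.chrom == c])
                for c in chroms}
    g = 0
    for c in chroms:
        prev = 0
        for s, e in occupied[c] + [(params.chrom_sizes[c], params.chrom_sizes[c])]:
            gap = s - prev
            glen = int(rng.integers(800, 1600))
            if gap > glen + 200 and g < params.n_genes:
                gs = prev + 100
                genes.append(Feature(id=f"GENE{g:04d}", chrom=c, start=gs,
                                     end=gs + glen,
                                     strand="+" if rng.random() < 0.5 else "-",
                                     kind="gene"))
                g += 1
            prev = e
    return genome, tes, genes, truth


def _domain_hit_table(truth, coverages, landmarks) -> pd.DataFrame:
    """Emulated HMM/LTR hit table: each domain hit's covered fraction equals
    the fraction of the consensus-domain interval present in the copy."""
    rows = []
    for row in truth.itertuples(index=False):
        cov = coverages[row.te_id]
        for name, interval in landmarks[row.family].items():
            frac = landmark_fraction(cov, interval)
            if frac > 0:
                rows.append((row.te_id, name, round(float(frac), 6)))
    return pd.DataFrame(rows, columns=["te_id", "domain", "covered_fraction"])


def planted_domains(truth: pd.DataFrame, coverages, landmarks,
                    min_coverage: float = 0.90) -> dict[str, frozenset]:
    """The ground-truth domain content implied by the planted coverage."""
    out = {}
    for row in truth.itertuples(index=False):
        cov = coverages[row.te_id]
        out[row.te_id] = frozenset(
            d for d, iv in landmarks[row.family].items()
            if landmark_fraction(cov, iv) > min_coverage)
    return out


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _cytosine_scan(seq: str):
    """Positions (0-based), strands and contexts of every cytosine (both
    strands, trinucleotide context; the last two bases of each strand are
    skipped)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    C, G = ord("C"), ord("G")
    n = len(arr)
    fwd = np.flatnonzero(arr[:n - 2] == C)
    fwd_ctx = np.where(arr[fwd + 1] == G, 0,
                       np.where(arr[fwd + 2] == G, 1, 2))
    rev = np.flatnonzero(arr[2:] == G) + 2
    rev_ctx = np.where(arr[rev - 1] == C, 0,
                       np.where(arr[rev - 2] == C, 1, 2))
    pos = np.concatenate([fwd, rev])
    strand = np.concatenate([np.zeros(len(fwd), dtype=np.int8),
                             np.ones(len(rev), dtype=np.int8)])
    ctx = np.concatenate([fwd_ctx, rev_ctx]).astype(np.int8)
    order = np.argsort(pos, kind="mergesort")
    return pos[order], strand[order], ctx[order]


def _roles_for(params, background: str) -> list[str]:
    base = ["wt", "polIV", "rdr6", "dcl3", "polV", "polIV_rdr6"]
    if params.include_extra_roles:
        base.insert(2, "rdr2")
    if background == "active":
        return ["ddm1" if r == "wt" else f"ddm1_{r}" for r in base]
    return base


def _simulate_methylome(params, rng, genome, tes, truth, background: str
                        ) -> dict[str, pd.DataFrame]:
    """One cytosine call table per genotype role for one background."""
    cat_col = f"category_{background}"
    ctx_names = np.array(["CG", "CHG", "CHH"])
    roles = _roles_for(params, background)
    out: dict[str, list[pd.DataFrame]] = {r: [] for r in roles}
    for chrom in sorted(genome):
        pos, strand, ctx = _cytosine_scan(genome[chrom])
        # TE membership of each cytosine
        chrom_tes = [(f.start, f.end, truth.index[truth["te_id"] == f.id][0])
                     for f in tes if f.chrom == chrom]
        te_idx = np.full(len(pos), -1, dtype=int)
        for s, e, ti in chrom_tes:
            lo, hi = np.searchsorted(pos, [s, e])
            te_idx[lo:hi] = ti
        base_p = np.array([params.background_levels[c] for c in ctx_names])
        in_te = te_idx >= 0
        cats = truth[cat_col].to_numpy()
        depth_all = rng.poisson(params.depth_mean, size=(len(roles), len(pos)))
        for ri, role in enumerate(roles):
            canon = mio.canonical_role(role, background)
            p = base_p[ctx]
            if in_te.any():
                te_cat = cats[te_idx[in_te]]
                p_chh = np.where(
                    te_cat == "NO_CHH", params.no_chh_level,
                    np.where(_affected(te_cat, canon),
                             params.chh_high / params.effect_factor,
                             params.chh_high))
                ctx_in = ctx[in_te]
                p_te = np.where(ctx_in == 0, params.cg_high,
                                np.where(ctx_in == 1, params.chg_high, p_chh))
                p = p.copy()
                p[in_te] = p_te
            n_total = depth_all[ri]
            n_meth = rng.binomial(n_total, p)
            covered = n_total > 0
            out[role].append(pd.DataFrame({
                "chrom": chrom,
                "pos": pos[covered] + 1,
                "strand": np.where(strand[covered] == 0, "+", "-"),
                "context": ctx_names[ctx[covered]],
                "n_meth": n_meth[covered],
                "n_total": n_total[covered],
            }))
    return {r: pd.concat(dfs, ignore_index=True) for r, dfs in out.items()}


def _affected(categories: np.ndarray, canonical_role: str) -> np.ndarray:
    if canonical_role == "ref":
        return np.zeros(len(categories), dtype=bool)
    table = {cat: canonical_role in roles for cat, roles in AFFECTED_ROLES.items()}
    return np.array([table[c] for c in categories])


# ---------------------------------------------------------------------------
# expression, small RNAs and cleavage
# ---------------------------------------------------------------------------

def _plan_expression(params, rng, truth: pd.DataFrame):
    """Plant competence, RNA-seq RPM and cleavage sites per TE.

    Active-background RDR6-RdDM targets are the (whole) planted
    RDR6-dependent-cleavage set: each gets at least one cleavage site that
    requires functional RDR6. A random slice of the remaining competent TEs
    is cleaved at primary (RDR6-independent) sites only.
    """
    n = len(truth)
    is_rdr6 = (truth["category_active"] == "RDR6_RDDM").to_numpy()
    extra = rng.random(n) < params.competent_extra_prob
    competent = is_rdr6 | extra
    primary_cleaved = competent & ~is_rdr6 & \
        (rng.random(n) < params.primary_cleaved_prob)

    lo_c, hi_c = params.rnaseq_rpm_competent
    lo_i, hi_i = params.rnaseq_rpm_incompetent
    rnaseq_rpm = np.where(extra, rng.uniform(lo_c, hi_c, size=n),
                          rng.uniform(lo_i, hi_i, size=n))

    site_rows = []  # te_id, background, site, rdr6_dependent
    lengths = truth["te_length"].to_numpy()
    for i in range(n):
        te_id = truth.loc[i, "te_id"]
        tlen = max(int(lengths[i]), 60)
        if is_rdr6[i]:
            dep_sites = set()
            for _ in range(int(rng.integers(1, 4))):
                dep_sites.add(int(rng.integers(20, tlen)))
            for s in sorted(dep_sites):
                site_rows.append((te_id, "active", s, True))
            if rng.random() < 0.3:  # an extra primary site is allowed
                s = int(rng.integers(20, tlen))
                while s in dep_sites:  # must stay distinguishable
                    s = int(rng.integers(20, tlen))
                site_rows.append((te_id, "active", s, False))
        elif primary_cleaved[i]:
            for _ in range(int(rng.integers(1, 3))):
                site_rows.append((te_id, "active", int(rng.integers(20, tlen)), False))
        # silent-context cleavage: retained, distinct or absent
        active_sites = [s for t, b, s, d in site_rows
                        if t == te_id and b == "active"]
        if active_sites:
            u = rng.random()
            if u < 0.40:   # retained (exact coordinate) in the silent context
                site_rows.append((te_id, "silent", active_sites[0], False))
            elif u < 0.60:  # cleaved at a distinct silent site
                s = int(rng.integers(20, tlen))
                while s in active_sites:
                    s = int(rng.integers(20, tlen))
                site_rows.append((te_id, "silent", s, False))
        elif competent[i] and rng.random() < 0.05:
            site_rows.append((te_id, "silent", int(rng.integers(20, tlen)), False))

    truth = truth.copy()
    truth["competent"] = competent
    truth["rnaseq_rpm"] = np.round(rnaseq_rpm, 4)
    truth["primary_cleaved"] = primary_cleaved
    truth_cleavage = pd.DataFrame(
        site_rows, columns=["te_id", "background", "site", "rdr6_dependent"])

    # PARE library layout: one RDR6-functional and one rdr6-mutant per context
    libraries = {
        "silent": (("PARE_col", True), ("PARE_rdr6", False)),
        "active": (("PARE_ddm1", True), ("PARE_ddm1_rdr6", False)),
    }
    pare_rows = []
    for row in truth_cleavage.itertuples(index=False):
        for lib, functional in libraries[row.background]:
            if row.rdr6_dependent and not functional:
                continue  # the site needs RDR6: absent from the mutant library
            pare_rows.append((row.te_id, row.site,
                              float(rng.uniform(*params.true_site_p)),
                              lib, row.background, functional))
    # decoy sites above the significance cutoff, in every library
    te_ids = truth["te_id"].to_numpy()
    for background, libs in libraries.items():
        for lib, functional in libs:
            for _ in range(params.n_false_sites):
                i = int(rng.integers(0, n))
                pare_rows.append((te_ids[i],
                                  int(rng.integers(20, max(int(lengths[i]), 60))),
                                  float(rng.uniform(*params.false_site_p)),
                                  lib, background, functional))
    pare = pd.DataFrame(pare_rows, columns=["feature_id", "site", "p_value",
                                            "library_id", "background",
                                            "rdr6_functional"])
    pare = pare.sort_values(["background", "library_id", "feature_id", "site"]
                            ).reset_index(drop=True)
    rnaseq = truth[["te_id", "rnaseq_rpm"]].rename(
        columns={"te_id": "feature_id", "rnaseq_rpm": "rpm"})
    return truth, truth_cleavage, pare, rnaseq


_SRNA_LIBS = ("sRNA_wt", "sRNA_rdr6", "sRNA_ddm1", "sRNA_ddm1_rdr6")


def _simulate_srna(params, rng, truth: pd.DataFrame):
    """Per-feature, per-size raw count tables for the four sRNA libraries.

    Pol IV/DCL3(/co-regulated) targets make 23-25 nt siRNAs regardless of
    RDR6; active RDR6 targets make 21-22 nt siRNAs only in ddm1 with
    functional RDR6. Low uniform noise everywhere else.
    """
    sizes = np.arange(18, 29)
    w24 = {23: 0.2, 24: 0.65, 25: 0.15}
    w2122 = {21: 0.45, 22: 0.55}
    rows = []
    for row in truth.itertuples(index=False):
        for lib in _SRNA_LIBS:
            background = "active" if "ddm1" in lib else "silent"
            rdr6_ok = "rdr6" not in lib
            cat = row.category_active if background == "active" else \
                row.category_silent
            mean = {s: params.srna_noise_mean for s in sizes}
            if cat in ("POLIV_RDDM", "DCL3_RDDM", "COREGULATED"):
                for s, w in w24.items():
                    mean[s] += params.sirna24_mean * w
            if cat == "RDR6_RDDM" and background == "active" and rdr6_ok:
                for s, w in w2122.items():
                    mean[s] += params.sirna2122_mean * w
            if cat == "RDR6_RDDM" and background == "silent" and rdr6_ok:
                for s, w in w2122.items():
                    mean[s] += 0.2 * params.sirna2122_mean * w
            counts = rng.poisson([mean[s] for s in sizes])
            for s, c in zip(sizes, counts):
                if c > 0:
                    rows.append((row.te_id, lib, int(s), int(c)))
    counts = pd.DataFrame(rows, columns=["feature_id", "library_id", "size",
                                         "count"])
    totals = {lib: params.srna_library_total for lib in _SRNA_LIBS}
    return counts, totals
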