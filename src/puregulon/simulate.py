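"""Synthetic data generator with known ground truth for every pipeline stage.

Emulates the data structure of a paired RIP-seq / knockdown RNA-seq /
co-IP-MS / RT-qPCR study of two RBP paralogues (PUM1 and PUM2):

* transcript sequences with 5'UTR/CDS/3'UTR extents and PUM-binding
  elements (PBEs) planted in the 3'UTRs of "bound" genes, plus optional
  cofactor-RBP motifs planted in "regulated" genes;
* negative-binomial abundance tables for IP/IgG/transcriptome libraries
  with a planted IP enrichment for bound genes, and for
  knockdown/control libraries with planted +-(kd_effect) shifts for
  regulated genes;
* replicate-level protein presence/absence matrices for co-IP mass
  spectrometry, with and without RNase treatment, with IgG background;
* Ct tables for RT-qPCR with two unaffected reference genes.

Every generator is a pure function of its :class:`SyntheticConfig`; one
global seed expands into independent per-stage substreams so stages can be
regenerated independently.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TranscriptRecord
from .motifs import BASES, expand_iupac, PBE_IUPAC

logger = logging.getLogger(__name__)

PUMS = ("PUM1", "PUM2")

#: Default cofactor-RBP motif panel: (name, IUPAC, planted occurrences per
#: regulated 3'UTR). Entries with rate 0 are negative controls in the style
#: of RBPMS/MBNL1 — RBPs with well-defined motifs that do not bind PUM —
#: and are never planted. The panel is chosen so that no control motif
#: shares a matching trinucleotide with any planted motif; otherwise
#: cross-matching (e.g. a CA-repeat planted motif partially matching a
#: CAC-rich control) makes the "unplanted" controls genuinely enriched.
DEFAULT_COFACTOR_MOTIFS: tuple[tuple[str, str, float], ...] = (
    ("IGF2BP1", "CAUCAUC", 2.0),
    ("PTBP1", "UCUUCUU", 2.0),
    ("HNRNPF", "GGGAGGG", 2.0),
    ("RBPMS", "CACNNCAC", 0.0),
    ("MBNL1", "YGCY", 0.0),
)


@dataclass
class SyntheticConfig:
    """Parameters of the simulated study.

    Defaults describe the emulated study conditions: 3 biological
    replicates, a 4-fold IP enrichment for bound mRNAs, a 50% abundance
    shift for regulated mRNAs upon knockdown, and replicate noise
    consistent with deep sequencing of a homogeneous cell line (see the
    methods note for the dispersion rationale).
    """

    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 3
    # fraction of genes bound by each paralogue (frac_common counts genes
    # bound by both and is included in both frac_bound_* values)
    frac_bound_p1: float = 0.15
    frac_bound_p2: float = 0.12
    frac_common: float = 0.05
    # regulation is only planted in bound genes
    frac_regulated: float = 0.6
    frac_repressed: float = 0.8
    ip_enrichment_fc: float = 4.0
    kd_effect: float = 0.5
    nb_dispersion: float = 0.005
    mean_abundance_log_mu: float = 6.0   # natural log of baseline abundance
    mean_abundance_log_sigma: float = 1.0
    region_length_means: tuple[int, int, int] = (150, 1200, 800)
    motif_rate_bound: float = 2.5        # expected planted PBEs per bound 3'UTR
    motif_rate_background: float = 0.0   # extra planted PBEs per kb, any region
    # (name, IUPAC, expected planted occurrences per regulated 3'UTR)
    cofactor_motifs: tuple[tuple[str, str, float], ...] = DEFAULT_COFACTOR_MOTIFS
    ms_n_proteins: int = 200
    ms_true_interactors: int = 30
    ms_frac_rna_dependent: float = 0.5
    ms_detection_dropout: float = 0.0
    ms_igg_noise_rate: float = 0.02
    qpcr_sd: float = 0.2
    library_size_range: tuple[float, float] = (0.7, 1.4)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("frac_bound_p1", "frac_bound_p2", "frac_common",
                     "frac_regulated", "frac_repressed"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_common > min(self.frac_bound_p1, self.frac_bound_p2):
            raise ValueError("frac_common cannot exceed either bound fraction")
        if self.frac_bound_p1 + self.frac_bound_p2 - self.frac_common > 1:
            raise ValueError("bound fractions exceed 1")
        for name in ("ip_enrichment_fc", "motif_rate_bound", "motif_rate_background",
                     "nb_dispersion", "ms_igg_noise_rate", "qpcr_sd",
                     "ms_detection_dropout"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.kd_effect <= 1:
            raise ValueError("kd_effect must be in [0, 1]")
        if min(self.region_length_means) <= 0:
            raise ValueError("region lengths must be > 0")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must be 0 < lo <= hi")
        bc = np.asarray(self.base_composition, float)
        if bc.shape != (4,) or (bc < 0).any() or not np.isclose(bc.sum(), 1.0):
            raise ValueError("base_composition must be 4 non-negative values summing to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region_length_means"] = list(self.region_length_means)
        d["cofactor_motifs"] = [list(m) for m in self.cofactor_motifs]
        d["library_size_range"] = list(self.library_size_range)
        d["base_composition"] = list(self.base_composition)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("region_length_means", "library_size_range", "base_composition"):
            if key in d:
                d[key] = tuple(d[key])
        if "cofactor_motifs" in d:
            d["cofactor_motifs"] = tuple(tuple(m) for m in d["cofactor_motifs"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted labels: what each downstream stage should recover."""

    genes: list[str]
    bound_by: dict[str, str]            # none | PUM1 | PUM2 | both
    regulated_by: dict[str, str]        # none | PUM1 | PUM2 | both (subset of bound)
    direction: dict[str, str]           # repressed | activated | none
    planted_pbe: dict[str, tuple[int, int, int]]
    planted_pbe_positions: dict[str, list[int]]
    planted_cofactor: dict[str, dict[str, int]]
    baseline_mean: dict[str, float]
    proteins: list[str] = field(default_factory=list)
    interactor_of: dict[str, str] = field(default_factory=dict)  # none | PUM1 | PUM2 | both
    rna_dependent: dict[str, bool] = field(default_factory=dict)

    def bound_set(self, pum: str) -> set[str]:
        return {g for g, b in self.bound_by.items() if b in (pum, "both")}

    def regulated_set(self, pum: str) -> set[str]:
        return {g for g, b in self.regulated_by.items() if b in (pum, "both")}

    def interactor_set(self, pum: str) -> set[str]:
        return {p for p, b in self.interactor_of.items() if b in (pum, "both")}


def _stage_rng(config: SyntheticConfig, stage: str) -> np.random.Generator:
    """Independent, reproducible substream for one generation stage."""
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Transcriptome with planted motifs
# ---------------------------------------------------------------------------

def _plant_words(seq: list[str], lo: int, hi: int, words: Sequence[str],
                 n: int, occupied: list[tuple[int, int]],
                 rng: np.random.Generator, gene: str, label: str) -> list[int]:
    """Embed ``n`` motif words at uniform non-overlapping positions in [lo, hi).

    Collisions with already-planted intervals are re-sampled up to 100
    times, then the occurrence is skipped with a log record. Returns the
    start positions actually embedded.
    """
    width = len(words[0])
    placed: list[int] = []
    if hi - lo < width:
        if n > 0:
            logger.info("%s: region too short for %s motif, skipping %d planned", gene, label, n)
        return placed
    for _ in range(n):
        for _attempt in range(100):
            start = int(rng.integers(lo, hi - width + 1))
            if all(start + width <= a or start >= b for a, b in occupied):
                word = words[int(rng.integers(len(words)))]
                seq[start : start + width] = list(word)
                occupied.append((start, start + width))
                placed.append(start)
                break
        else:
            logger.info("%s: could not place %s motif after 100 attempts, skipped", gene, label)
    return placed


def generate_transcriptome(config: SyntheticConfig) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Sample transcripts and the full ground-truth labelling.

    Region lengths are gamma-distributed around their configured means;
    background sequence is drawn from ``base_composition``; PBE words
    (uniform over the expansion of ``UGUAHAUW``) are planted in bound
    genes' 3'UTRs at Poisson(``motif_rate_bound``) and everywhere at
    Poisson(``motif_rate_background`` per kb); cofactor motifs are planted
    in regulated genes' 3'UTRs at their configured per-sequence rates.
    """
    rng = _stage_rng(config, "transcriptome")
    n = config.n_genes
    genes = [f"GENE{i + 1:05d}" for i in range(n)]

    # --- binding labels: counts forced by the configured fractions
    n_both = round(config.frac_common * n)
    n_p1 = round(config.frac_bound_p1 * n) - n_both
    n_p2 = round(config.frac_bound_p2 * n) - n_both
    order = rng.permutation(n)
    bound_by = dict.fromkeys(genes, "none")
    for i in order[:n_both]:
        bound_by[genes[i]] = "both"
    for i in order[n_both : n_both + n_p1]:
        bound_by[genes[i]] = "PUM1"
    for i in order[n_both + n_p1 : n_both + n_p1 + n_p2]:
        bound_by[genes[i]] = "PUM2"

    # --- regulation labels: planted only within bound genes
    regulated_by = dict.fromkeys(genes, "none")
    direction = dict.fromkeys(genes, "none")
    for g in genes:
        if bound_by[g] == "none" or rng.random() >= config.frac_regulated:
            continue
        if bound_by[g] == "both":
            regulated_by[g] = ("PUM1", "PUM2", "both")[int(rng.integers(3))]
        else:
            regulated_by[g] = bound_by[g]
        direction[g] = "repressed" if rng.random() < config.frac_repressed else "activated"

    # --- sequences with planted motifs
    pbe_words = sorted(expand_iupac(PBE_IUPAC))
    cof_words = {name: sorted(expand_iupac(iupac)) for name, iupac, _ in config.cofactor_motifs}
    base_p = np.asarray(config.base_composition, float)
    records: list[TranscriptRecord] = []
    planted_pbe: dict[str, tuple[int, int, int]] = {}
    planted_pbe_positions: dict[str, list[int]] = {}
    planted_cofactor: dict[str, dict[str, int]] = {}
    mean_lengths = config.region_length_means
    for g in genes:
        lens = [max(1, int(round(rng.gamma(4.0, m / 4.0)))) for m in mean_lengths]
        total = sum(lens)
        seq = list(rng.choice(list(BASES), size=total, p=base_p))
        bounds = [(0, lens[0]), (lens[0], lens[0] + lens[1]), (lens[0] + lens[1], total)]
        occupied: list[tuple[int, int]] = []
        counts = [0, 0, 0]
        positions: list[int] = []
        # chance-level planted background in every region
        if config.motif_rate_background > 0:
            for ri, (lo, hi) in enumerate(bounds):
                k = rng.poisson(config.motif_rate_background * (hi - lo) / 1000.0)
                placed = _plant_words(seq, lo, hi, pbe_words, k, occupied, rng, g, "background PBE")
                counts[ri] += len(placed)
                positions.extend(placed)
        # PBEs in the 3'UTR of bound genes
        if bound_by[g] != "none":
            k = rng.poisson(config.motif_rate_bound)
            placed = _plant_words(seq, *bounds[2], pbe_words, k, occupied, rng, g, "PBE")
            counts[2] += len(placed)
            positions.extend(placed)
        # cofactor motifs in the 3'UTR of regulated genes
        cof_counts: dict[str, int] = {}
        if regulated_by[g] != "none":
            for name, _iupac, rate in config.cofactor_motifs:
                k = rng.poisson(rate)
                placed = _plant_words(seq, *bounds[2], cof_words[name], k, occupied, rng, g, name)
                if placed:
                    cof_counts[name] = len(placed)
        records.append(TranscriptRecord(gene=g, sequence="".join(seq),
                                        utr5_len=lens[0], cds_len=lens[1], utr3_len=lens[2]))
        planted_pbe[g] = tuple(counts)
        planted_pbe_positions[g] = sorted(positions)
        planted_cofactor[g] = cof_counts

    baseline = {
        g: float(np.exp(rng.normal(config.mean_abundance_log_mu, config.mean_abundance_log_sigma)))
        for g in genes
    }

    # --- protein truth for the MS stage; planted cofactor RBPs (rate > 0)
    # appear by name and are always interactors of both paralogues, so the
    # motif-enrichment and interactome layers of the regulon can be joined
    planted_rbps = [name for name, _i, rate in config.cofactor_motifs if rate > 0]
    n_filler = max(config.ms_n_proteins - len(planted_rbps), 0)
    proteins = planted_rbps + [f"PROT{i + 1:04d}" for i in range(n_filler)]
    interactor_of = dict.fromkeys(proteins, "none")
    rna_dependent = dict.fromkeys(proteins, False)
    for name in planted_rbps:
        interactor_of[name] = "both"
        rna_dependent[name] = bool(rng.random() < config.ms_frac_rna_dependent)
    n_extra = min(max(config.ms_true_interactors - len(planted_rbps), 0), n_filler)
    chosen = rng.permutation(n_filler)[:n_extra]
    for j, i in enumerate(chosen):
        p = proteins[len(planted_rbps) + i]
        interactor_of[p] = ("PUM1", "PUM2", "both")[j % 3]
        rna_dependent[p] = bool(rng.random() < config.ms_frac_rna_dependent)

    truth = GroundTruth(
        genes=genes, bound_by=bound_by, regulated_by=regulated_by, direction=direction,
        planted_pbe=planted_pbe, planted_pbe_positions=planted_pbe_positions,
        planted_cofactor=planted_cofactor, baseline_mean=baseline,
        proteins=proteins, interactor_of=interactor_of, rna_dependent=rna_dependent,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def _nb_counts(means: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2.

    At dispersion -> 0 this degenerates to Poisson, which is used directly
    below a small cutoff for numerical stability.
    """
    means = np.asarray(means, float)
    if dispersion < 1e-9:
        return rng.poisson(means).astype(float)
    size = 1.0 / dispersion
    p = size / (size + means)
    return rng.negative_binomial(size, p).astype(float)


def _sample_table(genes: list[str], mean_per_gene: np.ndarray, condition: str,
                  config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.library_size_range
    cols = {}
    for r in range(1, config.n_replicates + 1):
        lib = rng.uniform(lo, hi)
        cols[f"{condition}_rep{r}"] = _nb_counts(mean_per_gene * lib, config.nb_dispersion, rng)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


def generate_rip_tables(config: SyntheticConfig, truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """IP-PUM1 / IP-PUM2 / IgG / transcriptome count tables.

    Bound genes' IP means are scaled by ``ip_enrichment_fc`` relative to
    both IgG and transcriptome baselines; library sizes vary within
    ``library_size_range`` across samples.
    """
    rng = _stage_rng(config, "rip")
    genes = truth.genes
    base = np.array([truth.baseline_mean[g] for g in genes])
    tables: dict[str, pd.DataFrame] = {}
    for pum, cond in (("PUM1", "IP_PUM1"), ("PUM2", "IP_PUM2")):
        bound = np.array([truth.bound_by[g] in (pum, "both") for g in genes])
        means = np.where(bound, base * config.ip_enrichment_fc, base)
        tables[cond] = _sample_table(genes, means, cond, config, rng)
    tables["IgG"] = _sample_table(genes, base, "IgG", config, rng)
    tables["transcriptome"] = _sample_table(genes, base, "transcriptome", config, rng)
    return tables


def generate_kd_tables(config: SyntheticConfig, truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """siPUM1 / siPUM2 / siControl count tables.

    Repressed targets rise by ``kd_effect`` in the matching knockdown
    (losing their repressor), activated targets fall by the same factor;
    all other genes are unchanged.
    """
    rng = _stage_rng(config, "kd")
    genes = truth.genes
    base = np.array([truth.baseline_mean[g] for g in genes])
    tables: dict[str, pd.DataFrame] = {}
    for pum, cond in (("PUM1", "siPUM1"), ("PUM2", "siPUM2")):
        factor = np.ones(len(genes))
        for i, g in enumerate(genes):
            if truth.regulated_by[g] in (pum, "both"):
                if truth.direction[g] == "repressed":
                    factor[i] = 1.0 + config.kd_effect
                else:
                    factor[i] = 1.0 - config.kd_effect
        tables[cond] = _sample_table(genes, base * factor, cond, config, rng)
    tables["siControl"] = _sample_table(genes, base, "siControl", config, rng)
    return tables


# ---------------------------------------------------------------------------
# Mass spectrometry presence tables
# ---------------------------------------------------------------------------

def generate_ms_tables(config: SyntheticConfig, truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Protein x replicate 0/1 detection matrices for each IP, +-RNase.

    Keys: ``{PUM1_IP,PUM2_IP,IgG}_{minus,plus}`` (minus/plus RNase A).
    True interactors are detected in every bait replicate of the relevant
    condition except for ``ms_detection_dropout`` losses; RNA-dependent
    interactors are absent whenever RNase was added. All tables carry
    nonspecific background detections at ``ms_igg_noise_rate``.
    """
    rng = _stage_rng(config, "ms")
    proteins = truth.proteins
    nrep = config.n_replicates
    detect = 1.0 - config.ms_detection_dropout
    tables: dict[str, pd.DataFrame] = {}
    for cond_name, bait in (("PUM1_IP", "PUM1"), ("PUM2_IP", "PUM2"), ("IgG", None)):
        for rnase, suffix in ((False, "minus"), (True, "plus")):
            mat = np.zeros((len(proteins), nrep), dtype=int)
            for i, p in enumerate(proteins):
                specific = (
                    bait is not None
                    and truth.interactor_of[p] in (bait, "both")
                    and not (rnase and truth.rna_dependent[p])
                )
                for r in range(nrep):
                    if specific and rng.random() < detect:
                        mat[i, r] = 1
                    elif rng.random() < config.ms_igg_noise_rate:
                        mat[i, r] = 1
            cols = [f"{cond_name}_{suffix}_rep{r + 1}" for r in range(nrep)]
            tables[f"{cond_name}_{suffix}"] = pd.DataFrame(
                mat, index=pd.Index(proteins, name="gene"), columns=cols
            )
    return tables


# ---------------------------------------------------------------------------
# RT-qPCR Ct tables
# ---------------------------------------------------------------------------

REFERENCE_GENES = ("ACTB", "GAPDH")
_REFERENCE_CT = {"ACTB": 17.0, "GAPDH": 18.0}


def generate_qpcr_tables(config: SyntheticConfig, truth: GroundTruth,
                         genes: Sequence[str]) -> pd.DataFrame:
    """Long-format Ct table for selected genes plus the two reference genes.

    Ct = baseline_ct - log2(relative abundance) + Normal(0, qpcr_sd);
    relative abundance follows the planted knockdown effect; reference
    genes are unaffected by either knockdown. Conditions: siControl,
    siPUM1, siPUM2.
    """
    rng = _stage_rng(config, "qpcr")
    unknown = [g for g in genes if g not in truth.baseline_mean]
    if unknown:
        raise ValueError(f"genes absent from ground truth: {unknown}")
    conditions = ("siControl", "siPUM1", "siPUM2")
    rows = []
    for g in list(genes) + list(REFERENCE_GENES):
        if g in REFERENCE_GENES:
            base_ct = _REFERENCE_CT[g]
        else:
            base_ct = 32.0 - np.log2(truth.baseline_mean[g])
        for cond in conditions:
            rel = 1.0
            if g not in REFERENCE_GENES and cond != "siControl":
                pum = cond.removeprefix("si")
                if truth.regulated_by[g] in (pum, "both"):
                    rel = (1.0 + config.kd_effect if truth.direction[g] == "repressed"
                           else 1.0 - config.kd_effect)
            for r in range(1, config.n_replicates + 1):
                ct = base_ct - np.log2(rel) + rng.normal(0.0, config.qpcr_sd)
                rows.append((g, cond, r, float(ct)))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


# ---------------------------------------------------------------------------
# Gene -> term annotation
# ---------------------------------------------------------------------------

def generate_gene_sets(config: SyntheticConfig, truth: GroundTruth,
                       n_random_terms: int = 10, random_term_size: int = 30) -> dict[str, set[str]]:
    """A flat gene -> term annotation with planted functional structure.

    One term per paralogue collects that paralogue's regulated genes (plus
    a few unbound genes, so the term is not a tautology), and
    ``n_random_terms`` terms of ``random_term_size`` genes each are drawn
    uniformly as unenriched background.
    """
    rng = _stage_rng(config, "gmt")
    sets: dict[str, set[str]] = {}
    unbound = [g for g in truth.genes if truth.bound_by[g] == "none"]
    for pum in PUMS:
        reg = sorted(truth.regulated_set(pum))
        extra = [unbound[i] for i in rng.permutation(len(unbound))[: max(3, len(reg) // 10)]]
        if reg:
            sets[f"{pum}_regulated_process"] = set(reg) | set(extra)
    for t in range(n_random_terms):
        size = min(random_term_size, len(truth.genes))
        idx = rng.permutation(len(truth.genes))[:size]
        sets[f"random_process_{t + 1:02d}"] = {truth.genes[i] for i in idx}
    return sets


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def truth_to_frames(truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground truth as (gene table, protein table) for TSV export."""
    gene_rows = []
    for g in truth.genes:
        cof = ";".join(f"{k}:{v}" for k, v in sorted(truth.planted_cofactor[g].items()))
        u5, cds, u3 = truth.planted_pbe[g]
        gene_rows.append((g, truth.bound_by[g], truth.regulated_by[g], truth.direction[g],
                          u5, cds, u3, cof, truth.baseline_mean[g]))
    gene_df = pd.DataFrame(gene_rows, columns=[
        "gene", "bound_by", "regulated_by", "direction",
        "pbe_utr5", "pbe_cds", "pbe_utr3", "cofactor_counts", "baseline_mean"])
    prot_df = pd.DataFrame(
        [(p, truth.interactor_of[p], int(truth.rna_dependent[p])) for p in truth.proteins],
        columns=["protein", "interactor_of", "rna_dependent"])
    return gene_df, prot_df
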