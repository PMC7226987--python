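"""End-to-end orchestration: one config, fixed output layout, manifest.

Stages run in dependency order: simulate (optional) -> call-targets ->
scan -> cofactors -> regulon -> qpcr. Each stage writes its outputs into
its own subdirectory of ``output_dir`` and communicates with later stages
only through those files; the manifest lists every produced file with a
content hash, so a re-run with the same config and seed is byte-identical
for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cofactors as cf
from . import io as pio
from . import motifs as pm
from . import qpcr as pq
from . import simulate as sim
from . import targets as tg

logger = logging.getLogger(__name__)

PUMS = ("PUM1", "PUM2")

#: input-file keys consumed by the analysis stages
INPUT_KEYS = (
    "fasta", "regions", "ip_pum1", "ip_pum2", "igg", "transcriptome",
    "si_pum1", "si_pum2", "si_control", "motifs", "gene_sets", "ct",
    "ms_pum1_minus", "ms_pum1_plus", "ms_pum2_minus", "ms_pum2_plus",
    "ms_igg_minus", "ms_igg_plus",
)


@dataclass
class Thresholds:
    """The pipeline's cutoffs (all inclusive where they gate a ratio)."""

    min_fc: float = 2.0
    kd_threshold: float = 0.20
    alpha: float = 0.05
    motif_p: float = 0.01
    germline_fold: float = 6.0
    expressed_floor: float = 0.5   # abundance floor defining the expressed background
    ratio_threshold: float = 2.0  # cofactor enrichment ratio gating regulon edges

    def violations(self) -> list[str]:
        out = []
        for name in ("min_fc", "kd_threshold", "motif_p", "germline_fold",
                     "expressed_floor", "ratio_threshold"):
            if getattr(self, name) <= 0:
                out.append(f"thresholds.{name} must be positive")
        if not 0 < self.alpha < 1:
            out.append("thresholds.alpha must be in (0, 1)")
        if not 0 < self.motif_p <= 1:
            out.append("thresholds.motif_p must be in (0, 1]")
        return out


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs or a simulation, thresholds, seed."""

    output_dir: str
    seed: int = 0
    synthetic: sim.SyntheticConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    qpcr_calibrator: str = "siControl"
    qpcr_references: tuple[str, ...] = pq.DEFAULT_REFERENCES

    def to_dict(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "inputs": dict(self.inputs),
            "thresholds": dataclasses.asdict(self.thresholds),
            "qpcr": {"calibrator": self.qpcr_calibrator,
                     "references": list(self.qpcr_references)},
        }
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        qp = d.get("qpcr", {})
        return cls(
            output_dir=d["output_dir"],
            seed=int(d.get("seed", 0)),
            synthetic=(sim.SyntheticConfig.from_dict(d["synthetic"])
                       if d.get("synthetic") is not None else None),
            inputs={k: str(v) for k, v in d.get("inputs", {}).items()},
            thresholds=Thresholds(**d.get("thresholds", {})),
            qpcr_calibrator=qp.get("calibrator", "siControl"),
            qpcr_references=tuple(qp.get("references", pq.DEFAULT_REFERENCES)),
        )


def validate_config(source) -> list[str]:
    """Validate a config path/dict/PipelineConfig; returns violations ([] = ok)."""
    try:
        if isinstance(source, PipelineConfig):
            config = source
        else:
            data = pio.read_yaml(source) if not isinstance(source, dict) else source
            config = PipelineConfig.from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        return [f"config does not parse: {exc}"]
    violations = config.thresholds.violations()
    if config.synthetic is None:
        missing = [k for k in INPUT_KEYS if k not in config.inputs]
        if missing:
            violations.append(f"inputs missing (and no synthetic section): {missing}")
        for key, path in config.inputs.items():
            if not Path(path).exists():
                violations.append(f"inputs.{key}: file not found: {path}")
    return violations


class StageError(RuntimeError):
    """Raised with the failing stage's name when a stage cannot run."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.outdir = outdir
        self.data = {"config": config.to_dict(), "stages": {}}

    def record(self, stage: str, files: list[Path]) -> None:
        self.data["stages"][stage] = {
            str(f.relative_to(self.outdir)): _sha256(f) for f in sorted(files)
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=1, sort_keys=True))
        return path


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> tuple[dict[str, str], list[Path]]:
    """Generate every downstream input from the synthetic config."""
    assert config.synthetic is not None
    sc = config.synthetic
    d = outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    records, truth = sim.generate_transcriptome(sc)
    rip = sim.generate_rip_tables(sc, truth)
    kd = sim.generate_kd_tables(sc, truth)
    ms = sim.generate_ms_tables(sc, truth)
    regulated = sorted(truth.regulated_set("PUM1") | truth.regulated_set("PUM2"))
    unregulated = [g for g in truth.genes if truth.regulated_by[g] == "none"]
    qpcr_genes = regulated[:6] + unregulated[:2]
    ct = sim.generate_qpcr_tables(sc, truth, qpcr_genes)
    gene_sets = sim.generate_gene_sets(sc, truth)

    files: list[Path] = []
    inputs: dict[str, str] = {}

    def put(key: str, path: Path) -> Path:
        inputs[key] = str(path)
        files.append(path)
        return path

    pio.write_fasta_with_regions(records, d / "transcripts.fasta", d / "regions.tsv")
    put("fasta", d / "transcripts.fasta")
    put("regions", d / "regions.tsv")
    table_keys = {"IP_PUM1": "ip_pum1", "IP_PUM2": "ip_pum2", "IgG": "igg",
                  "transcriptome": "transcriptome", "siPUM1": "si_pum1",
                  "siPUM2": "si_pum2", "siControl": "si_control"}
    for cond, table in {**rip, **kd}.items():
        key = table_keys[cond]
        pio.write_abundance_table(table, d / f"{cond}.tsv")
        put(key, d / f"{cond}.tsv")
    for name, table in ms.items():
        pio.write_abundance_table(table, d / f"ms_{name}.tsv")
        put(f"ms_{name.lower().replace('_ip', '')}", d / f"ms_{name}.tsv")
    pio.write_ct_table(ct, d / "qpcr_ct.tsv")
    put("ct", d / "qpcr_ct.tsv")
    motif_defs = [pio.MotifDefinition(name=n, kind="iupac", iupac=i)
                  for n, i, _r in sc.cofactor_motifs]
    if motif_defs:
        pio.write_motifs(motif_defs, d / "cofactor_motifs.tsv")
        put("motifs", d / "cofactor_motifs.tsv")
    pio.write_gene_sets(gene_sets, d / "gene_sets.gmt")
    put("gene_sets", d / "gene_sets.gmt")
    gene_df, prot_df = sim.truth_to_frames(truth)
    files.append(_write_tsv(gene_df, d / "truth_genes.tsv"))
    files.append(_write_tsv(prot_df, d / "truth_proteins.tsv"))
    pio.write_yaml(sc.to_dict(), d / "synthetic_config.yaml")
    files.append(d / "synthetic_config.yaml")
    return inputs, files


def stage_call_targets(inputs: dict[str, str], th: Thresholds, outdir: Path):
    """RIP enrichment + knockdown classification + intersection + Venn."""
    d = outdir / "targets"
    d.mkdir(parents=True, exist_ok=True)
    tables = {k: tg.normalize_libraries(pio.read_abundance_table(inputs[k]))
              for k in ("ip_pum1", "ip_pum2", "igg", "transcriptome",
                        "si_pum1", "si_pum2", "si_control")}
    files: list[Path] = []
    bound: dict[str, set[str]] = {}
    regulated: dict[str, dict[str, str]] = {}
    for pum, ip_key, si_key in (("PUM1", "ip_pum1", "si_pum1"), ("PUM2", "ip_pum2", "si_pum2")):
        enr = tg.rip_enrichment(tables[ip_key], tables["igg"], tables["transcriptome"],
                                min_fc=th.min_fc, alpha=th.alpha)
        calls = tg.classify_kd(tables[si_key], tables["si_control"],
                               threshold=th.kd_threshold, alpha=th.alpha)
        bound[pum] = {r.gene for r in enr if r.bound}
        regulated[pum] = tg.intersect_regulated(bound[pum], calls)
        files.append(_write_tsv(tg.records_to_frame(enr), d / f"enrichment_{pum}.tsv"))
        files.append(_write_tsv(tg.calls_to_frame(calls), d / f"kd_{pum}.tsv"))
        reg_df = pd.DataFrame(sorted(regulated[pum].items()), columns=["gene", "mode"])
        files.append(_write_tsv(reg_df, d / f"regulated_{pum}.tsv"))
    venn_rows = []
    for label, a, b in (
        ("bound", bound["PUM1"], bound["PUM2"]),
        ("regulated", set(regulated["PUM1"]), set(regulated["PUM2"])),
    ):
        v = tg.venn_partition(a, b)
        venn_rows.append({"comparison": label, "a_only": v.a_only, "b_only": v.b_only,
                          "common": v.common, "union": v.union,
                          "pct_common_of_union": v.pct_common_of_union})
    files.append(_write_tsv(pd.DataFrame(venn_rows), d / "venn_summary.tsv"))
    return bound, regulated, files


def stage_scan(inputs: dict[str, str], th: Thresholds, bound: dict[str, set[str]],
               regulated: dict[str, dict[str, str]], outdir: Path):
    """PBE content and regional distribution for bound and regulated sets."""
    d = outdir / "scan"
    d.mkdir(parents=True, exist_ok=True)
    records = pio.read_fasta_with_regions(inputs["fasta"], inputs["regions"])
    by_gene = {r.gene: r for r in records}
    rows = []
    hit_rows = []
    for pum in PUMS:
        for label, genes in ((f"{pum}_bound", bound[pum]),
                             (f"{pum}_regulated", set(regulated[pum]))):
            subset = [by_gene[g] for g in sorted(genes) if g in by_gene]
            if not subset:
                continue
            st = pm.motif_set_stats(subset, pm.PBE_IUPAC)
            region = st.region_pct or (float("nan"),) * 3
            rows.append({"set": label, "n": st.n_sequences,
                         "mean_pbe_per_sequence": st.mean_hits_per_sequence,
                         "frac_with_pbe": st.frac_with_at_least_one,
                         "pct_utr5": region[0], "pct_cds": region[1], "pct_utr3": region[2]})
            for rec in subset:
                for h in pm.count_motif_hits(rec, pm.PBE_IUPAC):
                    hit_rows.append({"set": label, "gene": h.gene, "start0": h.start,
                                     "width": h.width, "region": h.region, "motif": "PBE"})
    files = [
        _write_tsv(pd.DataFrame(rows), d / "pbe_summary.tsv"),
        _write_tsv(pd.DataFrame(hit_rows), d / "pbe_hits.tsv"),
    ]
    return by_gene, files


def stage_cofactors(inputs: dict[str, str], th: Thresholds, by_gene,
                    bound: dict[str, set[str]], regulated: dict[str, dict[str, str]],
                    seed: int, outdir: Path):
    """Interactor calls, cofactor-motif enrichment, term enrichment."""
    d = outdir / "cofactors"
    d.mkdir(parents=True, exist_ok=True)
    ms = {key: pio.read_presence_table(inputs[f"ms_{key}"])
          for key in ("pum1_minus", "pum1_plus", "pum2_minus", "pum2_plus",
                      "igg_minus", "igg_plus")}
    interactors = cf.call_interactors(
        {"minus": ms["pum1_minus"], "plus": ms["pum1_plus"]},
        {"minus": ms["pum2_minus"], "plus": ms["pum2_plus"]},
        {"minus": ms["igg_minus"], "plus": ms["igg_plus"]},
    )
    files = [_write_tsv(cf.interactors_to_frame(interactors), d / "interactors.tsv")]

    enrichments: dict[tuple[str, str], cf.CofactorEnrichment] = {}
    term_results: dict[tuple[str, str], list[cf.TermEnrichmentResult]] = {}
    if "motifs" in inputs:
        motif_defs = pio.read_motifs(inputs["motifs"])
        changed = set().union(*(set(r) for r in regulated.values()))
        negatives_pool = [r for g, r in by_gene.items()
                          if g not in bound["PUM1"] and g not in bound["PUM2"]
                          and g not in changed]
        gene_sets = pio.read_gene_sets(inputs["gene_sets"])
        background = set(by_gene)
        for pum in PUMS:
            reg_records = [by_gene[g] for g in sorted(regulated[pum]) if g in by_gene]
            if not reg_records or not negatives_pool:
                continue
            lengths = [len(r) for r in reg_records]
            negatives, report = cf.build_negative_set(
                negatives_pool, lengths, (0, float("inf")), seed=seed)
            for m in motif_defs:
                enr = cf.cofactor_enrichment(reg_records, negatives, m, pvalue=th.motif_p)
                enrichments[(pum, m.name)] = enr
                if enr.selected_genes:
                    term_results[(pum, m.name)] = cf.term_enrichment(
                        set(enr.selected_genes), background, gene_sets, alpha=th.alpha)
        files.append(_write_tsv(cf.enrichments_to_frame(enrichments), d / "cofactor_enrichment.tsv"))
        term_rows = [{"pum": pum, "rbp": rbp, **t.__dict__}
                     for (pum, rbp), ts in term_results.items() for t in ts]
        files.append(_write_tsv(pd.DataFrame(term_rows), d / "term_enrichment.tsv"))
    return interactors, enrichments, term_results, files


def stage_regulon(interactors, enrichments, term_results, th: Thresholds, outdir: Path):
    d = outdir / "regulon"
    d.mkdir(parents=True, exist_ok=True)
    graph = cf.build_regulon(interactors, enrichments, term_results,
                             ratio_threshold=th.ratio_threshold)
    pio.write_regulon(graph, d / "regulon.graphml", d / "regulon.json")
    return graph, [d / "regulon.graphml", d / "regulon.json"]


def stage_qpcr(inputs: dict[str, str], config: PipelineConfig, outdir: Path):
    d = outdir / "qpcr"
    d.mkdir(parents=True, exist_ok=True)
    ct = pq.CtTable(pio.read_ct_table(inputs["ct"]), reference_genes=config.qpcr_references)
    calibrator = config.qpcr_calibrator
    rows = []
    for gene in ct.genes:
        cal_dct = ct.delta_ct(gene, calibrator)
        for cond in ct.conditions:
            if cond == calibrator:
                continue
            rel = pq.relative_expression(ct, gene, cond, calibrator)
            sig = pq.significance(ct.delta_ct(gene, cond), cal_dct)
            rows.append({"gene": gene, "condition": cond, "fold": rel.fold,
                         "t_p": sig.t_p, "stars": sig.stars,
                         "shapiro_p_condition": sig.shapiro_p[0],
                         "shapiro_p_calibrator": sig.shapiro_p[1],
                         "normality_warning": sig.normality_warning})
    return [_write_tsv(pd.DataFrame(rows), d / "qpcr_folds.tsv")]


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the manifest dict."""
    violations = validate_config(config)
    if violations:
        raise StageError(f"config: {'; '.join(violations)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    inputs = dict(config.inputs)
    th = config.thresholds

    def run_stage(name, fn, *args):
        try:
            return fn(*args)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    if config.synthetic is not None:
        sim_inputs, files = run_stage("simulate", stage_simulate, config, outdir)
        inputs = {**sim_inputs, **inputs}
        manifest.record("simulate", files)
    missing = [k for k in ("ip_pum1", "ip_pum2", "igg", "transcriptome",
                           "si_pum1", "si_pum2", "si_control") if k not in inputs]
    if missing:
        raise StageError(f"stage 'call-targets' missing inputs: {missing}")

    bound, regulated, files = run_stage("call-targets", stage_call_targets, inputs, th, outdir)
    manifest.record("call-targets", files)
    by_gene, files = run_stage("scan", stage_scan, inputs, th, bound, regulated, outdir)
    manifest.record("scan", files)
    interactors, enrichments, term_results, files = run_stage(
        "cofactors", stage_cofactors, inputs, th, by_gene, bound, regulated,
        config.seed, outdir)
    manifest.record("cofactors", files)
    _graph, files = run_stage("regulon", stage_regulon, interactors, enrichments,
                              term_results, th, outdir)
    manifest.record("regulon", files)
    if "ct" in inputs:
        files = run_stage("qpcr", stage_qpcr, inputs, config, outdir)
        manifest.record("qpcr", files)
    manifest.write()
    return manifest.data
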