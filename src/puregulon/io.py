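"""On-disk formats: FASTA + region tables, abundance TSVs, motif files, GMT,
GraphML/JSON graphs, Ct tables, YAML configs.

Conventions: tab-separated values, UTF-8, ``#``-prefixed comment lines
allowed; coordinates 0-based half-open on the mature mRNA; RNA alphabet
internally (T accepted on input, canonicalized to U). Readers validate and
reject rather than silently coerce; every writer/reader pair round-trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import canonical_rna

REGION_COLUMNS = ("gene", "utr5_len", "cds_len", "utr3_len")


@dataclass(frozen=True)
class TranscriptRecord:
    """One representative mRNA per gene: sequence plus region extents.

    Regions are contiguous on the mature mRNA in the order 5'UTR, CDS,
    3'UTR; their lengths must sum to the sequence length. ``region_of``
    maps a 0-based position to its region name.
    """

    gene: str
    sequence: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self):
        object.__setattr__(self, "sequence", canonical_rna(self.sequence))
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError(f"{self.gene}: negative region length")
        if self.utr5_len + self.cds_len + self.utr3_len != len(self.sequence):
            raise ValueError(
                f"{self.gene}: region lengths exceed sequence or leave a gap "
                f"({self.utr5_len}+{self.cds_len}+{self.utr3_len} != {len(self.sequence)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> str:
        return self.sequence[: self.utr5_len]

    @property
    def cds(self) -> str:
        return self.sequence[self.utr5_len : self.utr5_len + self.cds_len]

    @property
    def utr3(self) -> str:
        return self.sequence[self.utr5_len + self.cds_len :]

    def region_of(self, pos: int) -> str:
        if not 0 <= pos < len(self.sequence):
            raise IndexError(f"{self.gene}: position {pos} outside [0, {len(self.sequence)})")
        if pos < self.utr5_len:
            return "utr5"
        if pos < self.utr5_len + self.cds_len:
            return "cds"
        return "utr3"


@dataclass
class MotifDefinition:
    """An RBP binding motif: either a degenerate IUPAC word or a PWM.

    PWMs are width x 4 probability matrices over A,C,G,U with rows summing
    to 1 (tolerance 1e-9 as written; 1e-6 accepted on read).
    """

    name: str
    kind: str  # "iupac" | "pwm"
    iupac: str | None = None
    pwm: np.ndarray | None = None
    source: str = ""

    def __post_init__(self):
        if self.kind == "iupac":
            if not self.iupac:
                raise ValueError(f"motif {self.name}: empty IUPAC string")
            from .motifs import IUPAC_CODES

            bad = set(self.iupac.upper()) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"motif {self.name}: invalid IUPAC letters {sorted(bad)}")
            object.__setattr__(self, "iupac", self.iupac.upper().replace("T", "U"))
        elif self.kind == "pwm":
            pwm = np.asarray(self.pwm, dtype=float)
            if pwm.ndim != 2 or pwm.shape[1] != 4:
                raise ValueError(f"motif {self.name}: PWM must be width x 4")
            if pwm.shape[0] < 4:
                raise ValueError(f"motif {self.name}: PWM width must be >= 4")
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"motif {self.name}: PWM rows must sum to 1")
            self.pwm = pwm
        else:
            raise ValueError(f"motif {self.name}: kind must be 'iupac' or 'pwm'")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


# ---------------------------------------------------------------------------
# FASTA + regions
# ---------------------------------------------------------------------------

def read_fasta_with_regions(fasta_path, regions_path) -> list[TranscriptRecord]:
    """Load transcripts, pairing each FASTA record with its region row.

    Every FASTA ID must have exactly one region row and vice versa; region
    lengths must sum to the sequence length. Errors name the offending gene.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record for gene {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    regions = _read_tsv(regions_path)
    missing = [c for c in REGION_COLUMNS if c not in regions.columns]
    if missing:
        raise ValueError(f"region table lacks columns {missing}")
    if regions["gene"].duplicated().any():
        dup = regions.loc[regions["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate region row for gene {dup!r}")
    region_map = regions.set_index("gene")
    fasta_only = set(seqs) - set(region_map.index)
    region_only = set(region_map.index) - set(seqs)
    if fasta_only or region_only:
        raise ValueError(
            f"gene mismatch between FASTA and regions: missing region rows for "
            f"{sorted(fasta_only)}; missing sequences for {sorted(region_only)}"
        )
    records = []
    for gene, seq in seqs.items():
        row = region_map.loc[gene]
        records.append(
            TranscriptRecord(
                gene=gene,
                sequence=seq,
                utr5_len=int(row["utr5_len"]),
                cds_len=int(row["cds_len"]),
                utr3_len=int(row["utr3_len"]),
            )
        )
    return records


def write_fasta_with_regions(records: Iterable[TranscriptRecord], fasta_path, regions_path) -> None:
    records = list(records)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.gene, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
    with open(regions_path, "w") as fh:
        fh.write("# region lengths in nt; regions contiguous as 5'UTR,CDS,3'UTR; 0-based half-open\n")
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.utr5_len}\t{r.cds_len}\t{r.utr3_len}\n")


# ---------------------------------------------------------------------------
# Abundance / presence tables
# ---------------------------------------------------------------------------

def parse_sample_columns(columns: Sequence[str]) -> dict[str, list[str]]:
    """Group sample columns ``<condition>_rep<k>`` by condition, in replicate order."""
    groups: dict[str, list[tuple[int, str]]] = {}
    for col in columns:
        if "_rep" not in col:
            raise ValueError(f"sample column {col!r} does not match '<condition>_rep<k>'")
        cond, _, rep = col.rpartition("_rep")
        try:
            k = int(rep)
        except ValueError:
            raise ValueError(f"sample column {col!r} has a non-integer replicate index") from None
        groups.setdefault(cond, []).append((k, col))
    return {cond: [c for _, c in sorted(v)] for cond, v in groups.items()}


def read_abundance_table(path) -> pd.DataFrame:
    """Read a gene x sample abundance TSV (first column ``gene``).

    Values must be numeric and non-negative; duplicate gene IDs are
    rejected. Sample headers are validated as ``<condition>_rep<k>`` and the
    grouping is stored in ``df.attrs['conditions']``.
    """
    df = _read_tsv(path)
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicate gene {dup!r}")
    df = df.set_index("gene")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValueError(f"{path}: non-numeric value at gene {row!r}, column {col!r}")
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise ValueError(f"{path}: negative value at gene {row!r}, column {col!r}")
        df[col] = vals.astype(float)
    df.attrs["conditions"] = parse_sample_columns(df.columns)
    return df


def write_abundance_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_presence_table(path) -> pd.DataFrame:
    """Protein x replicate 0/1 detection matrix."""
    df = read_abundance_table(path)
    bad = ~df.isin([0.0, 1.0]).all(axis=1)
    if bad.any():
        raise ValueError(f"{path}: presence table contains values other than 0/1 "
                         f"(first offending row: {df.index[bad][0]!r})")
    return df.astype(int)


# ---------------------------------------------------------------------------
# Motifs: MEME minimal format and IUPAC TSV
# ---------------------------------------------------------------------------

def read_motifs(path) -> list[MotifDefinition]:
    """Read motif definitions.

    MEME minimal files (detected by a ``MEME version`` header) yield PWM
    motifs; otherwise the file is a two-column TSV of name -> IUPAC word.
    """
    text = Path(path).read_text()
    if "MEME version" in text:
        return _parse_meme_minimal(text, source=str(path))
    motifs = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'name<TAB>IUPAC'")
        motifs.append(MotifDefinition(name=parts[0], kind="iupac", iupac=parts[1], source=str(path)))
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def _parse_meme_minimal(text: str, source: str) -> list[MotifDefinition]:
    motifs = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise ValueError(f"{source}: motif {name} lacks a letter-probability matrix")
                i += 1
            if i >= len(lines):
                raise ValueError(f"{source}: motif {name} lacks a letter-probability matrix")
            header = lines[i]
            width = None
            for tok_key, tok_val in zip(header.split(), header.split()[1:]):
                if tok_key == "w=":
                    width = int(tok_val)
            rows = []
            i += 1
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                vals = stripped.split()
                if len(vals) != 4:
                    raise ValueError(f"{source}: motif {name}: matrix row must have 4 probabilities")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    raise ValueError(f"{source}: motif {name}: malformed probability row {stripped!r}") from None
                i += 1
            pwm = np.asarray(rows)
            if width is not None and pwm.shape[0] != width:
                raise ValueError(f"{source}: motif {name}: declared w={width} but {pwm.shape[0]} rows")
            motifs.append(MotifDefinition(name=name, kind="pwm", pwm=pwm, source=source))
        else:
            i += 1
    if not motifs:
        raise ValueError(f"{source}: no MOTIF blocks found")
    return motifs


def write_motifs(motifs: Iterable[MotifDefinition], path) -> None:
    """Write motifs: MEME minimal if any PWM is present, else IUPAC TSV."""
    motifs = list(motifs)
    if any(m.kind == "pwm" for m in motifs):
        if not all(m.kind == "pwm" for m in motifs):
            raise ValueError("cannot mix PWM and IUPAC motifs in one MEME file")
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
            fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
            for m in motifs:
                fh.write(f"MOTIF {m.name}\n")
                fh.write(f"letter-probability matrix: alength= 4 w= {m.pwm.shape[0]} nsites= 20 E= 0\n")
                for row in m.pwm:
                    fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
                fh.write("\n")
    else:
        with open(path, "w") as fh:
            fh.write("# name<TAB>IUPAC\n")
            for m in motifs:
                fh.write(f"{m.name}\t{m.iupac}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and regulon graphs
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> dict[str, set[str]]:
    """GMT: term <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT term {parts[0]!r} has no genes")
        term = parts[0]
        if term in sets:
            raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
        genes = {g for g in parts[2:] if g}
        if not genes:
            raise ValueError(f"{path}:{lineno}: GMT term {term!r} has no genes")
        sets[term] = genes
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


def write_regulon(graph: nx.Graph, graphml_path, json_path=None) -> None:
    """Serialize a regulon graph to GraphML (and optionally JSON node-link)."""
    nx.write_graphml(graph, str(graphml_path))
    if json_path is not None:
        data = nx.node_link_data(graph, edges="edges")
        Path(json_path).write_text(json.dumps(data, indent=1, sort_keys=True))


def read_regulon(graphml_path) -> nx.Graph:
    return nx.read_graphml(str(graphml_path))


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def read_ct_table(path) -> pd.DataFrame:
    """Long-format Ct table: columns gene, condition, replicate, ct."""
    df = _read_tsv(path)
    required = {"gene", "condition", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table lacks columns {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if (df["ct"] <= 0).any():
        raise ValueError(f"{path}: non-positive Ct values present")
    df["replicate"] = df["replicate"].astype(int)
    return df[["gene", "condition", "replicate", "ct"]]


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data


def write_yaml(data: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True)
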