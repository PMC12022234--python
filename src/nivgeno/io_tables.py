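"""Readers and writers for the pipeline's delimited-text formats.

The canonical input is a tidy ("long") replicate table: one row per
sample x replicate x locus with two allele columns, where special tokens
mark missing, contaminated and disputed calls. Also here: marker-panel
descriptions (YAML/JSON), reference-haplotype FASTA, Genepop export and
the tabular writers for downstream results.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from .consensus_builder import SampleConsensus
from .genotype_model import (
    GenotypeCall,
    Locus,
    LocusPanel,
    ReplicateRecord,
    SampleMeta,
)
from .mtdna_screen import MitotypeRef


@dataclass(frozen=True)
class ReplicateTableDialect:
    """Column names and special tokens of a replicate table."""

    delimiter: str = "\t"
    missing_token: str = "NA"
    contamination_token: str = "CONT"
    disputed_token: str = "DISPUTED"
    sample_col: str = "sample_id"
    replicate_col: str = "replicate"
    locus_col: str = "locus"
    allele1_col: str = "allele1"
    allele2_col: str = "allele2"
    # optional metadata columns (ignored when absent)
    type_col: str = "sample_type"
    date_col: str = "collection_date"
    location_col: str = "location"

    def __post_init__(self) -> None:
        tokens = (self.missing_token, self.contamination_token, self.disputed_token)
        if len(set(tokens)) != 3:
            raise ValueError(f"special tokens must be mutually distinct, got {tokens}")
        cols = (
            self.sample_col, self.replicate_col, self.locus_col,
            self.allele1_col, self.allele2_col,
        )
        if len(set(cols)) != len(cols):
            raise ValueError(f"column names must be unique, got {cols}")


@dataclass
class ParseReport:
    """Row-level accounting of one replicate-table read."""

    n_rows: int = 0
    n_called: int = 0
    n_missing: int = 0
    n_contaminated: int = 0
    n_disputed: int = 0

    @property
    def total(self) -> int:
        return self.n_called + self.n_missing + self.n_contaminated + self.n_disputed


def _parse_cell_pair(a1: str, a2: str, dialect: ReplicateTableDialect, where: str) -> GenotypeCall:
    special = {
        dialect.missing_token: GenotypeCall.missing,
        dialect.contamination_token: GenotypeCall.contaminated,
        dialect.disputed_token: GenotypeCall.disputed,
    }
    if a1 in special or a2 in special:
        if a1 != a2:
            raise ValueError(f"{where}: special token must fill both allele columns ({a1!r}, {a2!r})")
        return special[a1]()
    if a1 == "" or a2 == "":
        raise ValueError(
            f"{where}: single allele given; homozygotes must be written as an equal pair"
        )
    try:
        return GenotypeCall.called(int(a1), int(a2))
    except ValueError as exc:
        raise ValueError(f"{where}: allele labels must be integer bp sizes ({a1!r}, {a2!r})") from exc


def read_replicate_table(
    path, dialect: ReplicateTableDialect, panel: LocusPanel
) -> Tuple[List[ReplicateRecord], List[SampleMeta], ParseReport]:
    """Read a long-layout replicate table.

    Returns one ``ReplicateRecord`` per (sample, replicate) with panel loci
    absent from the file scored missing, the sample metadata found in the
    optional columns, and a parse report whose status counts sum to the
    file's row count.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    required = [dialect.sample_col, dialect.replicate_col, dialect.locus_col,
                dialect.allele1_col, dialect.allele2_col]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise ValueError(f"{path}: missing required columns {absent}")

    unknown = sorted(set(df[dialect.locus_col]) - set(panel.locus_names))
    if unknown:
        rows = df.index[df[dialect.locus_col].isin(unknown)].tolist()
        raise ValueError(f"{path}: loci not in the panel: {unknown} (rows {rows[:20]})")

    report = ParseReport(n_rows=len(df))
    records: Dict[Tuple[str, int], ReplicateRecord] = {}
    metas: Dict[str, SampleMeta] = {}
    for idx, row in df.iterrows():
        sid = row[dialect.sample_col]
        rep = int(row[dialect.replicate_col])
        locus = row[dialect.locus_col]
        where = f"{path} row {idx}"
        call = _parse_cell_pair(row[dialect.allele1_col], row[dialect.allele2_col], dialect, where)
        key = (sid, rep)
        if key not in records:
            records[key] = ReplicateRecord(sid, rep, {})
        if locus in records[key].calls:
            raise ValueError(f"{where}: duplicate entry for locus {locus}")
        records[key].calls[locus] = call
        status = call.status.value
        setattr(report, f"n_{status}", getattr(report, f"n_{status}") + 1)
        if sid not in metas:
            metas[sid] = SampleMeta(
                sample_id=sid,
                sample_type=row.get(dialect.type_col, "scat") or "scat",
                collection_date=_parse_date(row.get(dialect.date_col, "")),
                location=row.get(dialect.location_col) or None,
            )

    out = []
    for key in sorted(records):
        rec = records[key]
        for name in panel.locus_names:
            rec.calls.setdefault(name, GenotypeCall.missing())
        rec.validate_against(panel)
        out.append(rec)
    return out, [metas[s] for s in sorted(metas)], report


def _parse_date(text: str) -> Optional[_dt.date]:
    # ISO-8601 only, for deterministic capture histories
    if not text:
        return None
    return _dt.date.fromisoformat(text)


def write_replicate_table(
    records: Sequence[ReplicateRecord],
    path,
    dialect: ReplicateTableDialect = ReplicateTableDialect(),
    metas: Optional[Sequence[SampleMeta]] = None,
) -> None:
    """Write records in the long layout ``read_replicate_table`` accepts."""
    meta_by_id = {m.sample_id: m for m in metas} if metas else {}
    rows = []
    token = {
        "missing": dialect.missing_token,
        "contaminated": dialect.contamination_token,
        "disputed": dialect.disputed_token,
    }
    for rec in records:
        for locus, call in rec.calls.items():
            if call.is_called:
                a1, a2 = (str(a) for a in call.alleles)
            else:
                a1 = a2 = token[call.status.value]
            row = {
                dialect.sample_col: rec.sample_id,
                dialect.replicate_col: rec.replicate_index,
                dialect.locus_col: locus,
                dialect.allele1_col: a1,
                dialect.allele2_col: a2,
            }
            meta = meta_by_id.get(rec.sample_id)
            if meta is not None:
                row[dialect.type_col] = meta.sample_type
                row[dialect.date_col] = meta.collection_date.isoformat() if meta.collection_date else ""
                if isinstance(meta.location, tuple):
                    row[dialect.location_col] = f"{meta.location[0]:.5f} {meta.location[1]:.5f}"
                else:
                    row[dialect.location_col] = meta.location or ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


def wide_to_long(
    df: pd.DataFrame,
    panel: LocusPanel,
    dialect: ReplicateTableDialect = ReplicateTableDialect(),
) -> pd.DataFrame:
    """Convenience converter from a wide table (two columns per locus).

    Expects columns ``<locus>.1`` / ``<locus>.2`` plus the sample and
    replicate columns; returns the equivalent long-layout frame.
    """
    rows = []
    for _, row in df.iterrows():
        for name in panel.locus_names:
            c1, c2 = f"{name}.1", f"{name}.2"
            if c1 not in df.columns:
                continue
            rows.append({
                dialect.sample_col: row[dialect.sample_col],
                dialect.replicate_col: row[dialect.replicate_col],
                dialect.locus_col: name,
                dialect.allele1_col: str(row[c1]),
                dialect.allele2_col: str(row[c2]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Marker panel description
# ---------------------------------------------------------------------------

def load_panel(path) -> LocusPanel:
    """Load a panel from a YAML/JSON file with a top-level ``loci`` list."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    loci = []
    for entry in spec["loci"]:
        loci.append(
            Locus(
                name=str(entry["name"]),
                multiplex_id=int(entry.get("multiplex", 1)),
                allele_size_range=tuple(entry.get("range", (100, 300))),
                is_sex_marker=bool(entry.get("sex_marker", False)),
            )
        )
    return LocusPanel(tuple(loci))


def dump_panel(panel: LocusPanel, path) -> None:
    spec = {
        "loci": [
            {
                "name": l.name,
                "multiplex": l.multiplex_id,
                "range": list(l.allele_size_range),
                "sex_marker": l.is_sex_marker,
            }
            for l in panel.loci
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Reference haplotypes (FASTA)
# ---------------------------------------------------------------------------

def read_haplotype_panel(fasta_path) -> List[MitotypeRef]:
    """Read a reference mitotype FASTA with ``name|specificity`` headers."""
    refs: List[MitotypeRef] = []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 2:
            raise ValueError(
                f"malformed header {rec.id!r}; expected 'name|specificity'"
            )
        name, spec = parts
        if name in seen:
            raise ValueError(f"duplicate mitotype name {name!r}")
        seen.add(name)
        refs.append(MitotypeRef(name=name, specificity=spec, sequence=str(rec.seq)))
    return refs


# ---------------------------------------------------------------------------
# Genepop export
# ---------------------------------------------------------------------------

def write_genepop(individuals: Sequence, panel: LocusPanel, path, title: str = "nivgeno export") -> None:
    """Write individual consensus genotypes as a Genepop file.

    Autosomal loci only; 3-digit allele coding (sizes must be < 1000 bp),
    missing genotypes written as ``000000``.
    """
    if not individuals:
        raise ValueError("Genepop export requires at least one individual")
    names = panel.autosomal_names
    lines = [title]
    lines.extend(names)
    lines.append("Pop")
    for ind in individuals:
        fields = []
        for locus in names:
            call = ind.consensus.get(locus, GenotypeCall.missing()) if hasattr(ind, "consensus") else ind.calls[locus]
            if call.is_called:
                a, b = call.alleles
                if a >= 1000 or b >= 1000:
                    raise ValueError(
                        f"allele size not encodable in 3 digits at {locus}: {call.alleles}"
                    )
                fields.append(f"{a:03d}{b:03d}")
            else:
                fields.append("000000")
        ident = getattr(ind, "individual_id", getattr(ind, "sample_id", "ind"))
        lines.append(f"{ident} ,  " + " ".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Result-table writers
# ---------------------------------------------------------------------------

def write_consensus_table(samples: Sequence[SampleConsensus], path, delimiter: str = "\t") -> None:
    """One row per sample x locus plus a per-sample summary row."""
    rows = []
    for s in samples:
        for locus, call in s.calls.items():
            rows.append({
                "sample_id": s.sample_id,
                "locus": locus,
                "allele1": call.alleles[0] if call.is_called else "",
                "allele2": call.alleles[1] if call.is_called else "",
                "status": call.status.value,
                "qi": round(s.qi_per_locus.get(locus, float("nan")), 4),
            })
        rows.append({
            "sample_id": s.sample_id,
            "locus": "__sample__",
            "allele1": "",
            "allele2": "",
            "status": "contaminated" if s.contaminated else "ok",
            "qi": round(s.mean_qi, 4),
        })
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_individual_table(individuals: Sequence, path, delimiter: str = "\t") -> None:
    rows = []
    for ind in individuals:
        rows.append({
            "individual_id": ind.individual_id,
            "n_samples": len(ind.sample_ids),
            "sex": ind.sex,
            "first_capture": ind.first_capture.isoformat() if ind.first_capture else "",
            "last_capture": ind.last_capture.isoformat() if ind.last_capture else "",
        })
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_membership_table(individuals: Sequence, path, delimiter: str = "\t") -> None:
    rows = [
        {"sample_id": sid, "individual_id": ind.individual_id}
        for ind in individuals
        for sid in ind.sample_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
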