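"""Readers, writers, bundled fixtures and provenance records.

Formats: measurement tables (TSV/CSV), aligned FASTA (via Biopython),
two-column species maps, newick trees (via dendropy), PHYLIP square distance
matrices, JSON reports and SVG idiograms. Three cleaned measurement tables
for the Kor-basin loaches are bundled; every cleaning edit is listed in the
fixture provenance file (``data/PROVENANCE.md``).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .karyotype import (
    ArmMeasurement,
    KaryotypeSummary,
    compute_metrics,
    classify,
    round2,
)
from .moldist import DistanceMatrix, SpeciesAlignment

FIXTURE_SPECIES = {
    "cobitis_linea": "Cobitis linea",
    "oxynoemacheilus_persa": "Oxynoemacheilus persa",
    "oxynoemacheilus_tongiorgii": "Oxynoemacheilus tongiorgii",
}

_PRINTED_COLS = ("printed_ta", "printed_ar", "printed_ci", "printed_ct")


def read_measurements(path: str | Path) -> tuple[list[ArmMeasurement], pd.DataFrame]:
    """Read an arm-measurement table (TSV or CSV, header required).

    Required columns: pair_id, long_arm, short_arm; optional printed_*
    columns are carried through in the returned frame. Malformed or invalid
    rows raise with the offending line identified.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"measurement table not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    required = {"pair_id", "long_arm", "short_arm"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")

    measurements = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            measurements.append(
                ArmMeasurement(
                    pair_id=int(row.pair_id),
                    long_arm=float(row.long_arm),
                    short_arm=float(row.short_arm),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: line {row_no}: {exc}") from None
    ids = [m.pair_id for m in measurements]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate pair ids")
    return measurements, df


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture table (e.g. 'cobitis_linea')."""
    if name not in FIXTURE_SPECIES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_SPECIES)}"
        )
    return Path(resources.files("karyocoi") / "data" / f"{name}.tsv")


def load_fixture(name: str) -> tuple[list[ArmMeasurement], pd.DataFrame]:
    """Load a bundled species table; see :data:`FIXTURE_SPECIES` for names."""
    return read_measurements(fixture_path(name))


def metrics_table(
    measurements: list[ArmMeasurement], *, rounded: bool = True
) -> pd.DataFrame:
    """Per-chromosome metrics table (presentation rounding optional)."""
    rows = []
    for m in measurements:
        met = compute_metrics(m)
        cls = classify(met.arm_ratio)
        rows.append(
            {
                "pair_id": m.pair_id,
                "long_arm": m.long_arm,
                "short_arm": m.short_arm,
                "total_len": round2(met.total_len) if rounded else met.total_len,
                "arm_ratio": round2(met.arm_ratio) if rounded else met.arm_ratio,
                "centromeric_index": round2(met.centromeric_index)
                if rounded
                else met.centromeric_index,
                "morph_class": cls,
            }
        )
    return pd.DataFrame(rows)


def write_karyotype_report(
    summary: KaryotypeSummary,
    measurements: list[ArmMeasurement],
    out_dir: str | Path,
    *,
    stem: str = "karyotype",
) -> dict[str, Path]:
    """Write the per-chromosome TSV and the JSON summary; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}_metrics.tsv"
    metrics_table(measurements).to_csv(tsv, sep="\t", index=False)
    js = out_dir / f"{stem}_summary.json"
    js.write_text(json.dumps(asdict(summary), indent=2) + "\n")
    return {"metrics": tsv, "summary": js}


def read_fasta(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Read an aligned FASTA; returns (taxa, sequences). Duplicate ids error."""
    taxa, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not taxa:
        raise ValidationError(f"{path}: no FASTA records")
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValidationError(f"{path}: duplicate taxon ids {dupes}")
    return tuple(taxa), tuple(seqs)


def write_fasta(path: str | Path, taxa, sequences) -> None:
    """Write FASTA wrapped at 70 columns."""
    records = [
        SeqRecord(Seq(s), id=t, description="") for t, s in zip(taxa, sequences)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (taxon_id, species), no header."""
    mapping: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}: line {line_no}: expected 2 columns")
        taxon, species = (p.strip() for p in parts)
        if taxon in mapping:
            raise ValidationError(f"{path}: duplicate taxon {taxon!r}")
        mapping[taxon] = species
    if not mapping:
        raise ValidationError(f"{path}: empty species map")
    return mapping


def write_species_map(path: str | Path, mapping: dict[str, str]) -> None:
    Path(path).write_text(
        "".join(f"{t}\t{s}\n" for t, s in mapping.items())
    )


def load_alignment(
    fasta_path: str | Path, species_map_path: str | Path | None = None
) -> SpeciesAlignment:
    """FASTA + optional species map → validated alignment.

    Without a map each taxon is its own species. Taxa present in exactly one
    of the two files are an error, listed by name.
    """
    taxa, seqs = read_fasta(fasta_path)
    if species_map_path is None:
        mapping = {t: t for t in taxa}
    else:
        mapping = read_species_map(species_map_path)
        unmatched = sorted(set(taxa) ^ set(mapping))
        if unmatched:
            raise ValidationError(
                f"taxa present in only one of alignment and species map: {unmatched}"
            )
    return SpeciesAlignment(taxa=taxa, sequences=seqs, species_map=mapping)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def write_newick(path: str | Path, tree: dendropy.Tree) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def write_phylip_matrix(path: str | Path, matrix: DistanceMatrix) -> None:
    """PHYLIP square distance matrix (relaxed names, tab-separated)."""
    n = len(matrix.taxa)
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, t in enumerate(matrix.taxa):
            cells = "\t".join(f"{matrix.values[i, j]:.6f}" for j in range(n))
            fh.write(f"{t}\t{cells}\n")


def read_phylip_matrix(path: str | Path) -> DistanceMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ValidationError(f"{path}: bad PHYLIP header") from None
    if len(lines) - 1 != n:
        raise ValidationError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    taxa, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValidationError(f"{path}: row has {len(parts) - 1} cells, expected {n}")
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(taxa=tuple(taxa), values=np.array(rows))


def load_style(path: str | Path | None):
    """Idiogram style from a TOML file; defaults where keys are absent.

    Recognized keys: glyph_width, slot_spacing, height_scale, margin,
    centromere_radius, label_font_size, diploid, and a [class_colors] table
    mapping morphology classes to colors.
    """
    import tomllib

    from .idiogram import IdiogramStyle

    if path is None:
        return IdiogramStyle()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    style = IdiogramStyle()
    colors = raw.pop("class_colors", None)
    if colors is not None:
        merged = dict(style.class_colors)
        merged.update(colors)
        raw["class_colors"] = merged
    unknown = set(raw) - set(style.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"{path}: unknown style keys {sorted(unknown)}")
    return style.with_overrides(**raw)


def write_provenance(
    out_dir: str | Path, command: str, params: dict, *, stem: str = "provenance"
) -> Path:
    """Record the exact run configuration so outputs can be reproduced."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}.json"
    record = {
        "package": "karyocoi",
        "version": __version__,
        "command": command,
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v
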