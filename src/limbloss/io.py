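"""Readers and writers for the pipeline's exchange formats.

Formats: per-CNE multi-FASTA directories (with a BED index for reference
coordinates), a MAF-like single-file block format, a TSV species manifest
plus newick tree, BED3/4/5 interval files, GFF3 (for TSS extraction), and
a YAML configuration mirroring :class:`~limbloss.datamodel.DetectionConfig`.

Everything round-trips: ``write(x)`` followed by ``read`` reproduces ``x``
field by field.  Coordinates are converted to 0-based half-open at this
boundary and nowhere else.
"""

from __future__ import annotations

import logging
import math
import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    ANCESTOR_PREFIX,
    CNEAlignment,
    DetectionConfig,
    Species,
    SpeciesTree,
    ValidationError,
    config_hash,
)
from .intervals import Interval, IntervalSet

logger = logging.getLogger("limbloss")

MANIFEST_COLUMNS = [
    "name",
    "limb_status",
    "lineage",
    "time_since_limb_loss",
    "substitution_rate",
]


# ---------------------------------------------------------------------------
# species manifest + tree
# ---------------------------------------------------------------------------

def read_species_manifest(
    manifest_path: str | os.PathLike, tree_path: str | os.PathLike
) -> tuple[list[Species], SpeciesTree]:
    df = pd.read_csv(manifest_path, sep="\t", dtype={"name": str})
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"manifest missing columns: {sorted(missing_cols)}")

    def _opt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return v

    species = [
        Species(
            name=row["name"],
            limb_status=row["limb_status"],
            lineage=_opt(row["lineage"]),
            time_since_limb_loss=_opt(row["time_since_limb_loss"]),
            substitution_rate=_opt(row["substitution_rate"]),
        )
        for _, row in df.iterrows()
    ]
    if len({s.name for s in species}) != len(species):
        raise ValidationError("duplicate species names in manifest")
    tree = SpeciesTree.from_newick(Path(tree_path).read_text(), unit="Myr")
    tree.validate_against(species)
    return species, tree


def write_species_manifest(
    species: Sequence[Species],
    tree: SpeciesTree,
    manifest_path: str | os.PathLike,
    tree_path: str | os.PathLike,
) -> None:
    rows = [
        {
            "name": s.name,
            "limb_status": s.limb_status,
            "lineage": s.lineage or "",
            "time_since_limb_loss": (
                "" if s.time_since_limb_loss is None else s.time_since_limb_loss
            ),
            "substitution_rate": (
                "" if s.substitution_rate is None else s.substitution_rate
            ),
        }
        for s in species
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest_path, sep="\t", index=False
    )
    Path(tree_path).write_text(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# CNE alignment sets
# ---------------------------------------------------------------------------

INDEX_NAME = "index.bed"


def _record_id(name: str, is_ancestor: bool) -> str:
    return ANCESTOR_PREFIX + name if is_ancestor else name


def _aln_from_records(
    cne_id: str,
    chrom: str,
    start: int,
    end: int,
    ref_species: str,
    records: Iterable[tuple[str, str]],
    known_species: set[str] | None,
) -> CNEAlignment:
    sequences: dict[str, str] = {}
    ancestors: dict[str, str] = {}
    for name, seq in records:
        if name.startswith(ANCESTOR_PREFIX):
            ancestors[name[len(ANCESTOR_PREFIX):]] = seq
        else:
            if known_species is not None and name not in known_species:
                raise ValidationError(
                    f"{cne_id}: unknown species {name!r} not in manifest"
                )
            if name in sequences:
                raise ValidationError(f"{cne_id}: duplicate record for {name!r}")
            sequences[name] = seq
    aln = CNEAlignment(
        cne_id=cne_id, chrom=chrom, start=start, end=end,
        ref_species=ref_species, sequences=sequences, ancestors=ancestors,
    )
    aln.validate()
    return aln


def read_alignment_set(
    path: str | os.PathLike, species_names: Iterable[str] | None = None
) -> list[CNEAlignment]:
    """Read a per-CNE multi-FASTA directory or a MAF-like block file.

    A directory must contain ``index.bed`` (chrom, start, end, cne_id,
    ref_species in the score column slot is not used — ref species is the
    5th column) plus one ``<cne_id>.fa`` per element.
    """
    path = Path(path)
    known = set(species_names) if species_names is not None else None
    if path.is_dir():
        index_path = path / INDEX_NAME
        if not index_path.exists():
            raise ValidationError(f"alignment directory lacks {INDEX_NAME}")
        index = pd.read_csv(
            index_path, sep="\t", header=None,
            names=["chrom", "start", "end", "cne_id", "ref_species"],
        )
        if index["cne_id"].duplicated().any():
            dup = index.loc[index["cne_id"].duplicated(), "cne_id"].iloc[0]
            raise ValidationError(f"duplicate cne_id {dup!r} in index")
        alns = []
        for _, row in index.iterrows():
            fa = path / f"{row.cne_id}.fa"
            records = [
                (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fa, "fasta")
            ]
            alns.append(
                _aln_from_records(
                    row.cne_id, row.chrom, int(row.start), int(row.end),
                    row.ref_species, records, known,
                )
            )
        return alns
    return _read_maf_like(path, known)


def write_alignment_set(alns: Sequence[CNEAlignment], path: str | os.PathLike) -> None:
    """Write a per-CNE multi-FASTA directory (with index.bed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    seen = set()
    with open(path / INDEX_NAME, "w") as idx:
        for aln in alns:
            if aln.cne_id in seen:
                raise ValidationError(f"duplicate cne_id {aln.cne_id!r}")
            seen.add(aln.cne_id)
            idx.write(
                f"{aln.chrom}\t{aln.start}\t{aln.end}\t{aln.cne_id}\t{aln.ref_species}\n"
            )
            records = [
                SeqRecord(Seq(seq), id=_record_id(name, False), description="")
                for name, seq in aln.sequences.items()
            ] + [
                SeqRecord(Seq(seq), id=_record_id(name, True), description="")
                for name, seq in aln.ancestors.items()
            ]
            SeqIO.write(records, path / f"{aln.cne_id}.fa", "fasta")


def _read_maf_like(path: Path, known: set[str] | None) -> list[CNEAlignment]:
    alns: list[CNEAlignment] = []
    seen: set[str] = set()
    header: dict | None = None
    records: list[tuple[str, str]] = []

    def _flush():
        nonlocal header, records
        if header is None:
            return
        if header["cne_id"] in seen:
            raise ValidationError(f"duplicate cne_id {header['cne_id']!r}")
        seen.add(header["cne_id"])
        alns.append(
            _aln_from_records(
                header["cne_id"], header["chrom"], int(header["start"]),
                int(header["end"]), header["ref"], records, known,
            )
        )
        header, records = None, []

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("a "):
            _flush()
            fields = dict(kv.split("=", 1) for kv in line[2:].split())
            for key in ("cne_id", "chrom", "start", "end", "ref"):
                if key not in fields:
                    raise ValidationError(f"line {lineno}: block header lacks {key}")
            header = fields
        elif line.startswith("s "):
            if header is None:
                raise ValidationError(f"line {lineno}: sequence outside a block")
            parts = line.split()
            if len(parts) != 3:
                raise ValidationError(f"line {lineno}: malformed s-line")
            records.append((parts[1], parts[2].upper()))
        else:
            raise ValidationError(f"line {lineno}: unrecognised line {line[:20]!r}")
    _flush()
    return alns


def write_maf_like(alns: Sequence[CNEAlignment], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for aln in alns:
            fh.write(
                f"a cne_id={aln.cne_id} chrom={aln.chrom} start={aln.start} "
                f"end={aln.end} ref={aln.ref_species}\n"
            )
            for name, seq in aln.sequences.items():
                fh.write(f"s {name} {seq}\n")
            for name, seq in aln.ancestors.items():
                fh.write(f"s {ANCESTOR_PREFIX}{name} {seq}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# intervals: BED and GFF3
# ---------------------------------------------------------------------------

def read_intervals(path: str | os.PathLike, scored: bool = False) -> IntervalSet:
    """Read BED3/BED4/BED5 into a sorted :class:`IntervalSet`.

    BED5 score lands in ``Interval.score`` (as float) when ``scored``;
    malformed coordinates raise with the offending line number.
    """
    intervals: list[Interval] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValidationError(f"{path}: line {lineno}: fewer than 3 BED fields")
        chrom, s, e = parts[0], int(parts[1]), int(parts[2])
        if s >= e:
            raise ValidationError(f"{path}: line {lineno}: start >= end ({s} >= {e})")
        name = parts[3] if len(parts) > 3 else None
        score = float(parts[4]) if scored and len(parts) > 4 else None
        intervals.append(Interval(chrom, s, e, name=name, score=score))
    if not intervals:
        logger.warning("%s: empty interval file", path)
    return IntervalSet(intervals)


def write_intervals(ivs: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(float(iv.score)))
            fh.write("\t".join(fields) + "\n")


def read_gff_tss(path: str | os.PathLike) -> IntervalSet:
    """Extract gene TSS points from GFF3 as 1-bp intervals.

    GFF is 1-based inclusive; the TSS becomes the 0-based position
    ``start - 1`` on '+' and ``end - 1`` on '-'.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    points: list[Interval] = []
    for gene in db.features_of_type("gene"):
        if gene.strand == "+":
            tss = gene.start - 1
        elif gene.strand == "-":
            tss = gene.end - 1
        else:
            raise ValidationError(
                f"gene {gene.id}: strand {gene.strand!r} unusable for TSS extraction"
            )
        name = gene.attributes.get("ID", [gene.id])[0]
        points.append(Interval(gene.seqid, tss, tss + 1, name=name))
    if not points:
        logger.warning("%s: no gene features found", path)
    return IntervalSet(points)


# ---------------------------------------------------------------------------
# configuration + run logging
# ---------------------------------------------------------------------------

def read_config(path: str | os.PathLike) -> DetectionConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return DetectionConfig.from_mapping(data.get("detection", data))


def write_config(cfg: DetectionConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"detection": cfg.to_mapping()}, fh, sort_keys=True)


def log_run(cfg: DetectionConfig, seed: int | None) -> None:
    """Record the replay coordinates of a run: version, config hash, seed."""
    from . import __version__

    logger.info(
        "limbloss %s | config %s | seed %s", __version__, config_hash(cfg), seed
    )
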