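"""Readers and writers for band matrices, FASTA, Ct tables and reports.

Two band-matrix dialects are accepted, auto-detected from the header:

* long form — columns ``locus_id  sample  condition  enzyme  present``,
  one row per digest call, ``present`` in {0, 1, NA};
* wide form — a ``locus_id`` column plus one 0/1/NA column per
  ``<sample>_<condition>_<EH|EM>`` combination.

Tab and comma delimiters are both accepted (sniffed from the header line).
All outputs are TSV with a trailing provenance comment so any report can be
regenerated from its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .bisulfite import BisulfiteRead, ReferenceSeq
from .ddct import CtRecord
from .errors import ParseError
from .msap_core import BandObservation

__all__ = [
    "read_band_matrix",
    "write_band_matrix",
    "observations_from_frame",
    "read_fasta_references",
    "read_fasta_reads",
    "read_ct_table",
    "write_report",
]

logger = logging.getLogger(__name__)

_LONG_COLUMNS = ["locus_id", "sample", "condition", "enzyme", "present"]
_ENZYMES = ("EH", "EM")


def _sniff_sep(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if "\t" in header else ","


def _parse_present(value, where: str):
    if pd.isna(value) or str(value).strip().upper() in ("NA", ""):
        return pd.NA
    text = str(value).strip()
    if text in ("0", "1"):
        return int(text)
    raise ParseError(f"{where}: cell value {value!r} is not 0/1/NA")


def read_band_matrix(path: str | Path) -> pd.DataFrame:
    """Read a band matrix in either dialect into the tidy long form.

    Returns a frame with columns locus_id, sample, condition, enzyme,
    present (nullable Int64; NA marks unscored digests).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    if list(raw.columns) == _LONG_COLUMNS:
        df = raw.copy()
    elif raw.columns[0] == "locus_id":
        df = _wide_to_long(raw, path)
    else:
        raise ParseError(
            f"{path}: header matches neither the long dialect {_LONG_COLUMNS} "
            f"nor the wide dialect (locus_id + <sample>_<condition>_<EH|EM>)")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        present = _parse_present(row.present, f"{path}:{i}")
        if row.enzyme not in _ENZYMES:
            raise ParseError(f"{path}:{i}: enzyme must be EH or EM, got {row.enzyme!r}")
        records.append((row.locus_id, row.sample, row.condition, row.enzyme, present))
    out = pd.DataFrame(records, columns=_LONG_COLUMNS)
    out["present"] = out["present"].astype("Int64")
    keys = out[["locus_id", "sample", "condition", "enzyme"]]
    dup = keys[keys.duplicated()]
    if not dup.empty:
        first = tuple(dup.iloc[0])
        raise ParseError(f"{path}: duplicate key {first}")
    logger.info("%s: %d band calls over %d loci", path, len(out),
                out["locus_id"].nunique())
    return out


def _wide_to_long(raw: pd.DataFrame, path: Path) -> pd.DataFrame:
    rows = []
    for col in raw.columns[1:]:
        parts = col.rsplit("_", 2)
        if len(parts) != 3 or parts[2] not in _ENZYMES:
            raise ParseError(
                f"{path}: wide column {col!r} is not <sample>_<condition>_<EH|EM>")
        sample, condition, enzyme = parts
        for locus, value in zip(raw["locus_id"], raw[col]):
            rows.append((locus, sample, condition, enzyme, value))
    return pd.DataFrame(rows, columns=_LONG_COLUMNS)


def write_band_matrix(path: str | Path, df: pd.DataFrame) -> None:
    """Write a tidy band frame in the long dialect (NA for missing calls)."""
    out = df[_LONG_COLUMNS].copy()
    out["present"] = out["present"].astype("string").fillna("NA")
    out.to_csv(path, sep="\t", index=False)


def observations_from_frame(
    df: pd.DataFrame, sample: str, condition: str
) -> list[BandObservation]:
    """Pair EH/EM calls per locus into BandObservations for one selection.

    A locus missing either digest call (or scored NA) yields a missing
    observation, which downstream counts exclude and report.
    """
    sel = df[(df["sample"] == sample) & (df["condition"] == condition)]
    if sel.empty:
        raise ParseError(f"no rows for sample={sample!r}, condition={condition!r}")
    pivot = sel.pivot_table(index="locus_id", columns="enzyme", values="present",
                            aggfunc="first")
    observations = []
    for locus_id, row in pivot.iterrows():
        eh, em = row.get("EH", pd.NA), row.get("EM", pd.NA)
        if pd.isna(eh) or pd.isna(em):
            observations.append(BandObservation(str(locus_id), 0, 0, missing=True))
        else:
            observations.append(BandObservation(str(locus_id), int(eh), int(em)))
    return observations


def read_fasta_references(path: str | Path) -> list[ReferenceSeq]:
    """Read reference sequences (multi-line FASTA, case-folded to upper)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty or not FASTA")
    return [ReferenceSeq(id=r.id, seq=str(r.seq).upper()) for r in records]


def read_fasta_reads(path: str | Path) -> list[BisulfiteRead]:
    """Read bisulfite reads; headers may carry ``id|sample|tissue|condition``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty or not FASTA")
    reads = []
    for r in records:
        fields = r.id.split("|")
        sample, tissue, condition = (fields + ["", "", ""])[1:4]
        reads.append(BisulfiteRead(id=fields[0], seq=str(r.seq).upper(),
                                   sample=sample, tissue=tissue, condition=condition))
    return reads


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a Ct CSV with columns gene, sample, condition, bio_rep, tech_rep, ct."""
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)))
    required = {"gene", "sample", "condition", "bio_rep", "tech_rep", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            ct = float(row.ct)
        except (TypeError, ValueError):
            logger.warning("%s: undetermined Ct for %s/%s; excluded",
                           path, row.gene, row.sample)
            continue
        records.append(CtRecord(gene=str(row.gene), sample=str(row.sample),
                                condition=str(row.condition),
                                bio_rep=int(row.bio_rep), tech_rep=int(row.tech_rep),
                                ct=ct))
    return records


def write_report(path: str | Path, df: pd.DataFrame,
                 config: dict | None = None) -> None:
    """Write a TSV report with a trailing provenance comment line."""
    config_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    with open(path, "w", encoding="utf-8") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write(f"# msapkit {__version__} config_hash={config_hash}\n")
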