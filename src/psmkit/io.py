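"""Readers and writers for the package's on-disk formats.

* PSM tables: tab-delimited with a documented header (see ``PSM_COLUMNS``);
  unknown columns are carried through untouched so that real search-engine
  exports remain loadable.
* Protein sequences: FASTA (via Bio.SeqIO).
* Contaminant lists: plain text, one peptide per line, ``#`` comments.
* Quant matrices: GCT 1.3 with ratio-count metadata columns.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import PlexDesign, PSMRecord, QuantMatrix

#: mandatory PSM-table columns, in canonical order (reporter columns are
#: appended per plex design as ``reporter_<channel>``)
PSM_COLUMNS = [
    "spectrum_id",
    "run_id",
    "plex_id",
    "fraction_id",
    "charge",
    "precursor_mh",
    "mass_error_ppm",
    "score",
    "delta_rank_score",
    "delta_fr_score",
    "bcs",
    "spi_pct",
    "sequence",
    "modifications",
    "loc_top_score",
    "loc_second_score",
    "is_decoy",
    "class_label",
    "purity_pct",
    "tmt_labeled",
    "proteins",
]

OPTIONAL_COLUMNS = ["tag_length"]


def format_modifications(mods) -> str:
    return ";".join(f"{pos}:{mod_type}" for pos, mod_type in mods)


def parse_modifications(text: str):
    if not text or (isinstance(text, float) and math.isnan(text)):
        return []
    mods = []
    for token in str(text).split(";"):
        pos, mod_type = token.split(":")
        mods.append((int(pos), mod_type))
    return mods


def _parse_bool(value, column, row):
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"row {row}: unparseable boolean in column {column!r}: {value!r}")


def _parse_float(value, column, row):
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row}: unparseable numeric in column {column!r}: {value!r}"
        ) from None


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def read_psm_table(path, design: PlexDesign):
    """Read a tab-delimited PSM table into validated :class:`PSMRecord` s.

    Row order is preserved.  Missing mandatory columns and unparseable
    numerics are hard errors naming the column / row; invariant violations
    are collected and raised with row numbers.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    reporter_cols = [c for c in frame.columns if c.startswith("reporter_")]
    expected = [f"reporter_{ch}" for ch in design.channels]
    if reporter_cols and sorted(reporter_cols) != sorted(expected):
        raise ValueError(
            f"reporter columns {sorted(reporter_cols)} do not match design"
            f" {design.plex_id!r} channels ({len(design.channels)} expected:"
            f" {expected})"
        )

    known = set(PSM_COLUMNS) | set(OPTIONAL_COLUMNS) | set(expected)
    extra_cols = [c for c in frame.columns if c not in known]

    records = []
    violations = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        loc = None
        if not _is_blank(row["loc_top_score"]):
            top = _parse_float(row["loc_top_score"], "loc_top_score", idx)
            second = (
                None
                if _is_blank(row["loc_second_score"])
                else _parse_float(row["loc_second_score"], "loc_second_score", idx)
            )
            loc = (top, second)
        reporters = None
        if reporter_cols:
            cells = [row[c] for c in expected]
            if not all(_is_blank(c) for c in cells):
                reporters = np.array(
                    [_parse_float(c, "reporter", idx) for c in cells]
                )
        tag_length = None
        if "tag_length" in frame.columns and not _is_blank(row["tag_length"]):
            tag_length = int(_parse_float(row["tag_length"], "tag_length", idx))
        record = PSMRecord(
            spectrum_id=row["spectrum_id"],
            run_id=row["run_id"],
            plex_id=row["plex_id"],
            fraction_id=row["fraction_id"],
            charge=int(_parse_float(row["charge"], "charge", idx)),
            precursor_mh=_parse_float(row["precursor_mh"], "precursor_mh", idx),
            mass_error_ppm=_parse_float(row["mass_error_ppm"], "mass_error_ppm", idx),
            score=_parse_float(row["score"], "score", idx),
            delta_rank_score=_parse_float(
                row["delta_rank_score"], "delta_rank_score", idx
            ),
            delta_fr_score=_parse_float(row["delta_fr_score"], "delta_fr_score", idx),
            bcs=_parse_float(row["bcs"], "bcs", idx),
            spi_pct=_parse_float(row["spi_pct"], "spi_pct", idx),
            sequence=str(row["sequence"]),
            modifications=parse_modifications(row["modifications"]),
            localization=loc,
            is_decoy=_parse_bool(row["is_decoy"], "is_decoy", idx),
            class_label=str(row["class_label"]),
            purity_pct=_parse_float(row["purity_pct"], "purity_pct", idx),
            tmt_labeled=_parse_bool(row["tmt_labeled"], "tmt_labeled", idx),
            reporter_intensities=reporters,
            candidate_proteins=(
                [] if _is_blank(row["proteins"]) else str(row["proteins"]).split(";")
            ),
            tag_length=tag_length,
            extras={c: row[c] for c in extra_cols},
        )
        errors = record.validate(n_channels=design.n_channels)
        if errors:
            violations.extend(f"row {idx}: {e}" for e in errors)
        records.append(record)
    if violations:
        raise ValueError("invalid PSM table:\n" + "\n".join(violations))
    return records


def write_psm_table(records, path, design: PlexDesign) -> None:
    """Write records to a tab-delimited table readable by read_psm_table."""
    reporter_cols = [f"reporter_{ch}" for ch in design.channels]
    has_reporters = any(r.reporter_intensities is not None for r in records)
    extra_cols = sorted({k for r in records for k in r.extras})
    rows = []
    for r in records:
        row = {
            "spectrum_id": r.spectrum_id,
            "run_id": r.run_id,
            "plex_id": r.plex_id,
            "fraction_id": r.fraction_id,
            "charge": r.charge,
            "precursor_mh": repr(r.precursor_mh),
            "mass_error_ppm": repr(r.mass_error_ppm),
            "score": repr(r.score),
            "delta_rank_score": repr(r.delta_rank_score),
            "delta_fr_score": repr(r.delta_fr_score),
            "bcs": repr(r.bcs),
            "spi_pct": repr(r.spi_pct),
            "sequence": r.sequence,
            "modifications": format_modifications(r.modifications),
            "loc_top_score": "" if r.localization is None else repr(r.localization[0]),
            "loc_second_score": (
                ""
                if r.localization is None or r.localization[1] is None
                else repr(r.localization[1])
            ),
            "is_decoy": str(r.is_decoy),
            "class_label": r.class_label,
            "purity_pct": repr(r.purity_pct),
            "tmt_labeled": str(r.tmt_labeled),
            "proteins": ";".join(r.candidate_proteins),
            "tag_length": "" if r.tag_length is None else r.tag_length,
        }
        if has_reporters:
            if r.reporter_intensities is None:
                row.update({c: "" for c in reporter_cols})
            else:
                row.update(
                    {
                        c: repr(float(v))
                        for c, v in zip(reporter_cols, r.reporter_intensities)
                    }
                )
        row.update({c: r.extras.get(c, "") for c in extra_cols})
        rows.append(row)
    columns = PSM_COLUMNS + ["tag_length"]
    if has_reporters:
        columns += reporter_cols
    columns += extra_cols
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict:
    """Read protein sequences keyed by the first token of each FASTA header."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_peptide_list(path) -> set:
    """Plain-text contaminant list: one peptide per line, '#' comments."""
    peptides = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                peptides.add(line)
    return peptides


def write_gct(matrix: QuantMatrix, path, row_meta: Optional[pd.DataFrame] = None):
    """Write a QuantMatrix as GCT 1.3; missing entries become 'NA'.

    Ratio counts are emitted as per-row metadata columns
    (``ratio_count_<channel>``) alongside any caller-supplied row metadata.
    """
    counts = pd.DataFrame(
        matrix.ratio_counts,
        index=list(matrix.feature_ids),
        columns=[f"ratio_count_{ch}" for ch in matrix.channels],
    )
    if row_meta is not None:
        row_meta = row_meta.reindex(list(matrix.feature_ids))
        meta = pd.concat([row_meta, counts], axis=1)
    else:
        meta = counts
    n_rows, n_cols = len(matrix.feature_ids), len(matrix.channels)
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{n_rows}\t{n_cols}\t{meta.shape[1]}\t0\n")
        header = ["id"] + list(meta.columns) + list(matrix.channels)
        fh.write("\t".join(str(h) for h in header) + "\n")
        for i, fid in enumerate(matrix.feature_ids):
            cells = [str(fid)] + [str(v) for v in meta.iloc[i]] + [
                "NA" if np.isnan(v) else repr(float(v)) for v in matrix.values[i]
            ]
            fh.write("\t".join(cells) + "\n")


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.3 data block as a DataFrame (metadata columns included)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.3":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        n_rows, n_cols, n_rowmeta = int(dims[0]), int(dims[1]), int(dims[2])
        frame = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
    if frame.shape != (n_rows, n_cols + n_rowmeta):
        raise ValueError("GCT dimension line does not match data block")
    return frame
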