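"""Reading and writing spectral cohorts.

Two on-disk formats are supported:

* **Wide CSV** — the package's native cohort format: metadata columns
  (``patient_id, class, bio_rep, tech_rep``) followed by one numeric column
  per wavenumber, headers in cm^-1, written high->low.
* **JCAMP-DX 4.24** — the standard infrared exchange format, read-only,
  one spectrum per file.  ``XYDATA=(X++(Y..Y))`` tables in AFFN or ASDF
  (SQZ / DIF / DUP) compression and ``XYPOINTS=(XY..XY)`` are understood.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import META_COLUMNS, SpectralDataset, Spectrum
from .errors import FormatError, IntegrityError, ParseError

_FLOAT_FMT = "%.12g"


def read_wide_csv(path, meta_columns=None) -> SpectralDataset:
    """Read a wide cohort CSV into a :class:`SpectralDataset`.

    Column order in the file is irrelevant; wavenumber columns are sorted
    high->low on ingest.  Raises :class:`FormatError` for missing metadata
    columns, :class:`ParseError` (with the row index) for non-numeric
    intensities, and :class:`IntegrityError` for duplicate replicates.
    """
    meta_columns = list(meta_columns) if meta_columns is not None else list(META_COLUMNS)
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in meta_columns if c not in table.columns]
    if missing:
        raise FormatError(f"{path.name}: missing metadata columns {missing}")
    spec_cols = [c for c in table.columns if c not in meta_columns]
    try:
        wn = np.array([float(c) for c in spec_cols])
    except ValueError as exc:
        raise FormatError(
            f"{path.name}: non-numeric wavenumber header ({exc})"
        ) from None
    order = np.argsort(-wn)
    spec_cols = [spec_cols[i] for i in order]
    wn = wn[order]

    raw = table[spec_cols]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        raise ParseError(
            f"{path.name}: non-numeric intensity in data row {int(bad[0])}"
        )

    meta = table[meta_columns].copy()
    for col in ("bio_rep", "tech_rep"):
        if col in meta.columns:
            meta[col] = meta[col].astype(int)
    return SpectralDataset(values, wn, meta)


def write_wide_csv(ds: SpectralDataset, path) -> Path:
    """Write a cohort as wide CSV (meta first, wavenumbers high->low).

    Deterministic: the same dataset always produces byte-identical files,
    and ``read_wide_csv`` round-trips it within the write precision.
    """
    path = Path(path)
    out = ds.meta[META_COLUMNS].copy()
    header = [_FLOAT_FMT % w for w in ds.axis]
    spec = pd.DataFrame(ds.matrix, columns=header, index=out.index)
    pd.concat([out, spec], axis=1).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------

_SQZ = {c: v for v, c in enumerate("@ABCDEFGHI")}
_SQZ.update({c: -(v + 1) for v, c in enumerate("abcdefghi")})
_DIF = {"%": 0}
_DIF.update({c: v + 1 for v, c in enumerate("JKLMNOPQR")})
_DIF.update({c: -(v + 1) for v, c in enumerate("jklmnopqr")})
# DUP digit n: the preceding ordinate/difference occurs n times in total
_DUP = {c: v + 1 for v, c in enumerate("STUVWXYZs")}

_TOKEN = re.compile(r"[@A-Za-z%][0-9.]*|[+-]?[0-9]+(?:\.[0-9]+)?(?:[eE][+-]?[0-9]+)?")


def _decode_asdf_line(line: str):
    """Decode one XYDATA line -> (x, y-values, ended_in_dif).

    AFFN numbers, SQZ ordinates, DIF differences and DUP counts may be mixed
    on a line; the leading token is always the abscissa.
    """
    tokens = _TOKEN.findall(line)
    if not tokens:
        return None
    x = float(tokens[0])
    ys: list[float] = []
    last_was_dif = False
    for tok in tokens[1:]:
        head = tok[0]
        if head in _DUP:
            if not ys:
                raise ParseError("DUP with no preceding ordinate")
            count = _DUP[head]
            if len(tok) > 1:
                raise ParseError(f"malformed DUP token {tok!r}")
            if last_was_dif:
                step = ys[-1] - (ys[-2] if len(ys) > 1 else 0.0)
                for _ in range(count - 1):
                    ys.append(ys[-1] + step)
            else:
                ys.extend([ys[-1]] * (count - 1))
        elif head in _DIF:
            if not ys:
                raise ParseError("DIF with no preceding ordinate")
            digits = tok[1:]
            value = float(str(_DIF[head]) + digits) if digits else float(_DIF[head])
            if _DIF[head] < 0:
                value = -float(str(-_DIF[head]) + digits) if digits else value
            ys.append(ys[-1] + value)
            last_was_dif = True
        elif head in _SQZ:
            digits = tok[1:]
            mag = float(str(abs(_SQZ[head])) + digits) if digits else float(abs(_SQZ[head]))
            ys.append(-mag if _SQZ[head] < 0 else mag)
            last_was_dif = False
        else:
            ys.append(float(tok))
            last_was_dif = False
    return x, ys, last_was_dif


def read_jcampdx(path) -> Spectrum:
    """Read a single spectrum from a JCAMP-DX 4.24 file.

    Supports ``##XYDATA=(X++(Y..Y))`` with AFFN or SQZ/DIF/DUP ordinates
    (including the per-line Y-value check emitted after DIF lines) and
    ``##XYPOINTS=(XY..XY)``.  ``##TITLE`` populates ``patient_id``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None
    block_type = None
    for ln in lines:
        ln = ln.split("$$")[0].rstrip()
        if not ln.strip():
            continue
        if ln.startswith("##"):
            key, _, value = ln[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("XYDATA", "XYPOINTS"):
                mode = block_type = key.lower()
                continue
            if key == "END":
                mode = None
                continue
            fields[key] = value
            mode = None
        elif mode is not None:
            data_lines.append(ln)

    if block_type is None or not data_lines:
        raise FormatError(f"{path.name}: no ##XYDATA or ##XYPOINTS block")

    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))
    npoints = int(float(fields["NPOINTS"])) if "NPOINTS" in fields else None

    if block_type == "xypoints":
        xs, ys = _parse_xypoints(data_lines)
        xs = [x * xfactor for x in xs]
        ys = [y * yfactor for y in ys]
    else:
        xs, ys = _parse_xydata(data_lines, yfactor, fields)

    if npoints is not None and len(ys) != npoints:
        raise IntegrityError(
            f"{path.name}: NPOINTS={npoints} but decoded {len(ys)} ordinates"
        )
    title = fields.get("TITLE", "")
    return Spectrum(np.array(xs), np.array(ys), patient_id=title)


def _parse_xypoints(data_lines):
    xs, ys = [], []
    for ln in data_lines:
        nums = [float(t) for t in ln.replace(";", " ").replace(",", " ").split()]
        if len(nums) % 2:
            raise ParseError(f"odd token count in XYPOINTS line: {ln!r}")
        xs.extend(nums[0::2])
        ys.extend(nums[1::2])
    return xs, ys


def _parse_xydata(data_lines, yfactor, fields):
    ys_raw: list[float] = []
    prev_dif = False
    for ln in data_lines:
        decoded = _decode_asdf_line(ln)
        if decoded is None:
            continue
        _, line_ys, ended_dif = decoded
        if prev_dif and line_ys:
            # first ordinate after a DIF line is a check value duplicating
            # the previous line's final ordinate
            if ys_raw and abs(line_ys[0] - ys_raw[-1]) > 0.5 * max(1.0, abs(ys_raw[-1]) * 1e-6):
                raise IntegrityError(
                    f"Y-value check failed: {line_ys[0]} vs {ys_raw[-1]}"
                )
            line_ys = line_ys[1:]
        ys_raw.extend(line_ys)
        prev_dif = ended_dif
    if not ys_raw:
        raise FormatError("empty XYDATA block")
    n = len(ys_raw)
    # FIRSTX/LASTX are already in real units; XFACTOR applies only to the
    # abscissa values printed in the table, which we do not use for the grid.
    firstx = float(fields.get("FIRSTX", 0.0))
    lastx = float(fields.get("LASTX", firstx + n - 1))
    xs = np.linspace(firstx, lastx, n)
    ys = [y * yfactor for y in ys_raw]
    return list(xs), ys
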