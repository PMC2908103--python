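"""GAL layout and intensity-table I/O, plus the layout consistency audit.

A GAL (GenePix Array List) file is an ATF-container, tab-delimited text
file mapping spot coordinates (block, column, row) to a Name and an ID.
On a dye calibration slide the Name field holds the nominal dye
concentration for dilution spots ("1.47E+05"), "0" for blanks, and words
("Buffer", "Marker") for control columns; the ID field holds the dye.

The vendor also ships a human-readable description table (the "manual")
assigning a density or role to each column.  The two documents are
supposed to agree — :func:`check_layout_consistency` audits them column by
column and reports every disagreement, including the classic
role-versus-density conflict where the manual declares a column "Buffer"
while the GAL file assigns it a numeric dye concentration.

Spot intensities travel in a small explicit CSV dialect::

    spot_id,block,column,row,series,channel,pmt_gain,x_nominal,signal,saturated

with UTF-8 encoding, "." decimal separator, and an empty ``x_nominal``
for buffer/marker spots.  GAL coordinates are 1-based (GAL convention);
any 0-based internal indexing stays out of this module's files.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, LayoutValidationError
from .fitting import ScanObservation
from .model import DEFAULT_CEILING
from .simulate import Role, SlideColumn, SlideLayout

__all__ = [
    "GalRecord",
    "ColumnVerdict",
    "ConsistencyReport",
    "parse_density",
    "read_gal",
    "write_gal",
    "read_intensity_table",
    "write_intensity_table",
    "read_manual_table",
    "write_manual_table",
    "check_layout_consistency",
]

INTENSITY_COLUMNS = ("spot_id", "block", "column", "row", "series",
                     "channel", "pmt_gain", "x_nominal", "signal", "saturated")

_EXP_SPACES = re.compile(r"([0-9.])\s*([eE])\s*([+-]?)\s*(\d+)")


@dataclass(frozen=True)
class GalRecord:
    """One GAL row: 1-based spot coordinates plus Name and ID fields."""

    block: int
    column: int
    row: int
    name: str
    id: str

    def __post_init__(self) -> None:
        if min(self.block, self.column, self.row) < 1:
            raise LayoutValidationError(
                f"GAL coordinates are 1-based positive integers, got "
                f"({self.block}, {self.column}, {self.row})"
            )


def parse_density(text: str) -> float:
    """Parse a density token, tolerating spaces inside the exponent.

    Vendor tables print scientific notation with embedded spaces
    ("1.47E + 05"); those parse identically to "1.47E+05".  Raises
    ``ValueError`` for non-numeric text.
    """
    cleaned = _EXP_SPACES.sub(r"\1\2\3\4", text.strip().strip('"'))
    return float(cleaned)


def _role_for_name(name: str) -> tuple[str, float | None]:
    """Map a GAL/manual Name field to (role, density)."""
    token = name.strip().strip('"')
    try:
        density = parse_density(token)
    except ValueError:
        low = token.lower()
        if low == "buffer":
            return Role.BUFFER, None
        if low in ("marker", "position marker"):
            return Role.MARKER, None
        raise FormatError(f"unrecognized Name field {name!r}: neither a "
                          "density nor Buffer/Marker")
    if density == 0:
        return Role.BLANK, 0.0
    if density < 0:
        raise FormatError(f"negative density {name!r}")
    return Role.DILUTION, density


def _name_for_column(col: SlideColumn) -> str:
    if col.role == Role.DILUTION:
        # repr round-trips the float exactly through write→read
        return repr(float(col.density))
    if col.role == Role.BLANK:
        return "0"
    if col.role == Role.BUFFER:
        return "Buffer"
    return "Marker"


# ---------------------------------------------------------------------------
# GAL


def write_gal(layout: SlideLayout, path: str | Path) -> None:
    """Write ``layout`` as a GenePix Array List (ATF) file."""
    path = Path(path)
    lines = ["ATF\t1.0"]
    header = ['"Type=GenePix ArrayList V1.0"', '"BlockCount=1"',
              f'"Replicates={layout.replicates_per_column}"']
    lines.append(f"{len(header)}\t5")
    lines.extend(header)
    lines.append("Block\tColumn\tRow\tName\tID")
    for col in sorted(layout.columns, key=lambda c: c.index):
        name = _name_for_column(col)
        for r in range(1, layout.replicates_per_column + 1):
            lines.append(f"1\t{col.index}\t{r}\t{name}\t{col.dye}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _split_gal_line(line: str) -> list[str]:
    return [tok.strip().strip('"') for tok in line.rstrip("\n").split("\t")]


def read_gal(path: str | Path) -> tuple[SlideLayout, list[GalRecord]]:
    """Parse a GAL file into a :class:`SlideLayout` and its records.

    Accepts plain and quoted tab-delimited fields.  Numeric Name fields
    become nominal densities, "0" a blank, "Buffer"/"Marker" roles.
    Malformed headers raise :class:`FormatError` with the line number;
    duplicate coordinates raise :class:`LayoutValidationError`.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].split("\t")[0].strip().upper() == "ATF":
        raise FormatError(f"{path}: line 1: not an ATF file (expected 'ATF' "
                          "as the first token)")
    try:
        n_header = int(_split_gal_line(lines[1])[0])
    except (IndexError, ValueError):
        raise FormatError(f"{path}: line 2: expected '<n_headers>\\t"
                          "<n_columns>'") from None
    col_line_no = 2 + n_header
    if col_line_no >= len(lines):
        raise FormatError(f"{path}: line {col_line_no + 1}: missing column "
                          "header line")
    columns = [c.lower() for c in _split_gal_line(lines[col_line_no])]
    try:
        pos = {f: columns.index(f) for f in ("block", "column", "row",
                                             "name", "id")}
    except ValueError as exc:
        raise FormatError(f"{path}: line {col_line_no + 1}: missing GAL "
                          f"column: {exc}") from None

    records: list[GalRecord] = []
    seen: set[tuple[int, int, int]] = set()
    for i, line in enumerate(lines[col_line_no + 1:], start=col_line_no + 2):
        if not line.strip():
            continue
        toks = _split_gal_line(line)
        try:
            rec = GalRecord(block=int(toks[pos["block"]]),
                            column=int(toks[pos["column"]]),
                            row=int(toks[pos["row"]]),
                            name=toks[pos["name"]],
                            id=toks[pos["id"]])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: malformed record "
                              f"({exc})") from None
        coord = (rec.block, rec.column, rec.row)
        if coord in seen:
            raise LayoutValidationError(
                f"{path}: line {i}: duplicate spot coordinate {coord}")
        seen.add(coord)
        records.append(rec)

    if not records:
        raise FormatError(f"{path}: no spot records")

    by_col: dict[int, list[GalRecord]] = {}
    for rec in records:
        by_col.setdefault(rec.column, []).append(rec)
    cols = []
    replicates = max(len(v) for v in by_col.values())
    for idx in sorted(by_col):
        recs = by_col[idx]
        names = {r.name for r in recs}
        if len(names) > 1:
            raise LayoutValidationError(
                f"{path}: column {idx} mixes Name values {sorted(names)}")
        role, density = _role_for_name(recs[0].name)
        cols.append(SlideColumn(index=idx, role=role, dye=recs[0].id,
                                density=density))
    layout = SlideLayout(columns=tuple(cols),
                         replicates_per_column=replicates)
    return layout, records


# ---------------------------------------------------------------------------
# intensity tables


def write_intensity_table(observations: Sequence[ScanObservation],
                          layout: SlideLayout | None,
                          path: str | Path) -> None:
    """Write observations in the intensity CSV dialect.

    Spot coordinates are reconstructed as block 1, column = series index,
    row = running replicate number within the series.
    """
    path = Path(path)
    counters: dict[int, int] = {}
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(INTENSITY_COLUMNS)
        for ob in observations:
            row = counters.get(ob.series_index, 0) + 1
            counters[ob.series_index] = row
            w.writerow([
                f"s{ob.series_index:02d}r{row:03d}", 1, ob.series_index, row,
                ob.series_index, ob.channel,
                "" if ob.pmt_gain is None else repr(float(ob.pmt_gain)),
                "" if ob.x_nominal is None else repr(float(ob.x_nominal)),
                repr(float(ob.signal)), int(ob.saturated),
            ])


def read_intensity_table(path: str | Path,
                         ceiling: float = DEFAULT_CEILING,
                         channel: str | None = None,
                         pmt_gain: float | None = None
                         ) -> list[ScanObservation]:
    """Read an intensity CSV into :class:`ScanObservation` records.

    The saturation flag is the stored flag OR a signal at/above
    ``ceiling``.  ``channel``/``pmt_gain`` override the file's columns
    when given.  Missing required columns and negative signals raise
    :class:`FormatError` naming the column / row.
    """
    path = Path(path)
    out: list[ScanObservation] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in INTENSITY_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s): "
                              f"{', '.join(missing)}")
        for i, rec in enumerate(reader, start=2):
            try:
                signal = float(rec["signal"])
            except ValueError:
                raise FormatError(f"{path}: row {i}: non-numeric signal "
                                  f"{rec['signal']!r}") from None
            if signal < 0:
                raise FormatError(f"{path}: row {i}: negative signal "
                                  f"{signal}")
            x_raw = (rec["x_nominal"] or "").strip()
            x_nom = parse_density(x_raw) if x_raw else None
            gain_raw = (rec["pmt_gain"] or "").strip()
            gain = float(gain_raw) if gain_raw else None
            stored_flag = str(rec["saturated"]).strip().lower() in ("1", "true")
            out.append(ScanObservation(
                series_index=int(rec["series"]),
                x_nominal=x_nom,
                signal=signal,
                channel=channel if channel is not None else rec["channel"],
                pmt_gain=pmt_gain if pmt_gain is not None else gain,
                saturated=stored_flag or signal >= ceiling,
            ))
    return out


# ---------------------------------------------------------------------------
# manual (slide description) tables


def write_manual_table(layout: SlideLayout, path: str | Path) -> None:
    """Write the two-column slide description CSV (series, density/role)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["series", "density_or_role"])
        for col in sorted(layout.columns, key=lambda c: c.index):
            w.writerow([col.index, _name_for_column(col)])


def read_manual_table(path: str | Path,
                      replicates_per_column: int = 1) -> SlideLayout:
    """Read a slide description CSV (``series,density_or_role``).

    "Buffer", "Marker" and "0" map to their roles; anything else must be
    a density, with embedded exponent spaces tolerated ("1.47E + 05").
    """
    path = Path(path)
    cols = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for need in ("series", "density_or_role"):
            if need not in header:
                raise FormatError(f"{path}: missing required column "
                                  f"{need!r}")
        for i, rec in enumerate(reader, start=2):
            try:
                idx = int(rec["series"])
            except ValueError:
                raise FormatError(f"{path}: row {i}: non-integer series "
                                  f"{rec['series']!r}") from None
            role, density = _role_for_name(rec["density_or_role"])
            cols.append(SlideColumn(index=idx, role=role, density=density))
    if not cols:
        raise FormatError(f"{path}: no rows")
    return SlideLayout(columns=tuple(cols),
                       replicates_per_column=replicates_per_column)


# ---------------------------------------------------------------------------
# consistency audit


@dataclass(frozen=True)
class ColumnVerdict:
    """Audit outcome for one slide column."""

    column: int
    verdict: str  # match | mismatch | missing
    detail: str
    manual_value: str
    gal_value: str


@dataclass
class ConsistencyReport:
    """Column-by-column comparison of a manual table against a GAL layout."""

    verdicts: list[ColumnVerdict]
    notes: list[str] = field(default_factory=list)

    def count(self, verdict: str) -> int:
        return sum(1 for v in self.verdicts if v.verdict == verdict)

    @property
    def n_match(self) -> int:
        return self.count("match")

    @property
    def n_mismatch(self) -> int:
        return self.count("mismatch")

    @property
    def n_missing(self) -> int:
        return self.count("missing")

    @property
    def consistent(self) -> bool:
        return self.n_mismatch == 0 and self.n_missing == 0

    def to_dict(self) -> dict:
        return {
            "counts": {"match": self.n_match, "mismatch": self.n_mismatch,
                       "missing": self.n_missing},
            "consistent": self.consistent,
            "notes": list(self.notes),
            "columns": [vars(v) for v in self.verdicts],
        }

    def to_text(self) -> str:
        lines = [f"Layout consistency audit: {self.n_match} match, "
                 f"{self.n_mismatch} mismatch, {self.n_missing} missing"]
        lines += [f"  note: {n}" for n in self.notes]
        for v in self.verdicts:
            if v.verdict != "match":
                lines.append(f"  column {v.column}: {v.verdict.upper()} — "
                             f"{v.detail}")
        return "\n".join(lines)


def _column_label(col: SlideColumn) -> str:
    if col.role == Role.DILUTION:
        return f"density {col.density:.3G}"
    return col.role


def check_layout_consistency(manual: SlideLayout,
                             gal: SlideLayout,
                             tolerance: float = 0.01) -> ConsistencyReport:
    """Audit ``manual`` against ``gal`` column by column.

    Densities match when their relative difference (against the larger
    magnitude) is within ``tolerance`` (default 1%); density comparison
    is symmetric.  Role-versus-density conflicts — e.g. the manual calls
    a column "buffer" while the GAL assigns it a concentration — are
    mismatches quoting both claims and their direction.  Differing column
    counts are noted and the audit continues on the overlap.
    """
    man_cols = {c.index: c for c in manual.columns}
    gal_cols = {c.index: c for c in gal.columns}
    notes = []
    if set(man_cols) != set(gal_cols):
        notes.append(
            f"column sets differ: manual has {len(man_cols)} "
            f"(indices {min(man_cols)}..{max(man_cols)}), GAL has "
            f"{len(gal_cols)} (indices {min(gal_cols)}..{max(gal_cols)}); "
            "auditing the overlap")
    verdicts = []
    for idx in sorted(set(man_cols) | set(gal_cols)):
        m, g = man_cols.get(idx), gal_cols.get(idx)
        if m is None or g is None:
            src = "manual" if m is None else "GAL"
            verdicts.append(ColumnVerdict(
                idx, "missing", f"column absent from the {src} source",
                "-" if m is None else _column_label(m),
                "-" if g is None else _column_label(g)))
            continue
        m_lab, g_lab = _column_label(m), _column_label(g)
        m_num = m.density if m.role in (Role.DILUTION, Role.BLANK) else None
        g_num = g.density if g.role in (Role.DILUTION, Role.BLANK) else None
        if m_num is not None and g_num is not None:
            scale = max(abs(m_num), abs(g_num))
            if abs(m_num - g_num) <= tolerance * scale:
                verdicts.append(ColumnVerdict(idx, "match",
                                              "densities agree", m_lab, g_lab))
            else:
                verdicts.append(ColumnVerdict(
                    idx, "mismatch",
                    f"manual assigns {m_lab}, GAL assigns {g_lab} "
                    f"(relative difference "
                    f"{abs(m_num - g_num) / scale:.3G} > {tolerance:.3G})",
                    m_lab, g_lab))
        elif m.role == g.role:
            verdicts.append(ColumnVerdict(idx, "match",
                                          f"both sources say {m.role}",
                                          m_lab, g_lab))
        else:
            verdicts.append(ColumnVerdict(
                idx, "mismatch",
                f"manual claims {m_lab} but GAL claims {g_lab}",
                m_lab, g_lab))
    return ConsistencyReport(verdicts=verdicts, notes=notes)
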