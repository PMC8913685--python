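"""Dated ring-width series: Tucson/rwl interchange and basal area increment conversion.

A tree's annual basal area increment (BAI) is the ring-to-ring difference in
stem cross-sectional area at breast height, ``BAI_t = pi * (R_t^2 - R_{t-1}^2)``.
Radii are reconstructed *outside-in* from the diameter measured at sampling
(DBH), so a missed pith inflates the innermost reconstructed radius rather
than corrupting the recent, climate-relevant increments.

Working unit is mm^2 throughout; divide by 100 for cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "RwlParseError",
    "DataInconsistencyError",
    "read_rwl",
    "write_rwl",
    "rings_to_bai",
    "attach_previous_ba",
    "network_bai_table",
    "MM2_PER_CM2",
]

MM2_PER_CM2 = 100.0

#: Tucson stop markers and the measurement precision (mm) they imply.
_STOP_PRECISION = {999: 0.01, -9999: 0.001}


class RwlParseError(ValueError):
    """Malformed Tucson/rwl content (reported with the 1-based line number)."""


class DataInconsistencyError(ValueError):
    """Ring widths and DBH are geometrically incompatible."""


@dataclass
class RingSeries:
    """One tree's dated ring-width series plus its sampling diameter.

    widths run oldest -> youngest, in mm; ``first_year`` dates ``widths[0]``.
    """

    tree_code: str
    site_id: str
    first_year: int
    widths: np.ndarray
    dbh_mm: float

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError(f"tree {self.tree_code}: widths must be a non-empty 1-d array")
        if not np.all(self.widths > 0):
            raise ValueError(f"tree {self.tree_code}: all ring widths must be > 0 mm")
        if self.dbh_mm < 2.0 * float(self.widths.sum()) - 1e-6:
            raise DataInconsistencyError(
                f"tree {self.tree_code}: dbh {self.dbh_mm:.2f} mm is smaller than twice the "
                f"cumulative ring width {2 * self.widths.sum():.2f} mm"
            )

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.widths.size - 1


# ---------------------------------------------------------------------------
# Tucson / rwl reading and writing
# ---------------------------------------------------------------------------

def read_rwl(path, site_id: str | None = None, dbh: dict[str, float] | None = None) -> list[RingSeries]:
    """Read a Tucson/rwl file into :class:`RingSeries`.

    Both common dialects are accepted and the measurement precision is
    inferred from the stop marker: ``999`` terminates 0.01 mm data, ``-9999``
    terminates 0.001 mm data. Values are returned in mm.

    ``dbh`` maps tree code -> DBH in mm; without it the DBH defaults to twice
    the cumulative width (pith assumed reached).
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            code = line[:8].strip()
            if not code:
                raise RwlParseError(f"{path}:{lineno}: missing series code")
            body = line[8:].split()
            if not body:
                raise RwlParseError(f"{path}:{lineno}: missing decade year")
            try:
                decade = int(body[0])
            except ValueError as exc:
                raise RwlParseError(f"{path}:{lineno}: malformed decade year {body[0]!r}") from exc
            values = []
            for tok in body[1:]:
                try:
                    values.append(int(tok))
                except ValueError as exc:
                    raise RwlParseError(f"{path}:{lineno}: malformed value {tok!r}") from exc
            if code not in raw:
                raw[code] = []
                order.append(code)
            year = decade
            for v in values:
                raw[code].append((year, v))
                year += 1

    out: list[RingSeries] = []
    for code in order:
        tokens = raw[code]
        vals = [v for _, v in tokens]
        # dialect resolved per series: a -9999 anywhere marks 0.001 mm data
        # (999 is then a legal width); otherwise the first 999 terminates
        # 0.01 mm data
        if -9999 in vals:
            stop_at = vals.index(-9999)
            scale = _STOP_PRECISION[-9999]
        elif 999 in vals:
            stop_at = vals.index(999)
            scale = _STOP_PRECISION[999]
        else:
            raise RwlParseError(f"{path}: series {code!r} has no stop marker (999 or -9999)")
        pairs = tokens[:stop_at]
        if len(tokens) > stop_at + 1:
            raise RwlParseError(f"{path}: data after stop marker for series {code!r}")
        if not pairs:
            raise RwlParseError(f"{path}: series {code!r} is empty")
        years = np.array([p[0] for p in pairs])
        if not np.all(np.diff(years) == 1):
            raise RwlParseError(f"{path}: series {code!r} has non-consecutive years")
        widths = np.array([p[1] for p in pairs], dtype=float) * scale
        dbh_mm = (dbh or {}).get(code, 2.0 * float(widths.sum()))
        out.append(
            RingSeries(
                tree_code=code,
                site_id=site_id if site_id is not None else code[:3],
                first_year=int(years[0]),
                widths=widths,
                dbh_mm=dbh_mm,
            )
        )
    return out


def write_rwl(series: list[RingSeries], path, precision: float | None = None) -> None:
    """Write series in Tucson format.

    ``precision=0.01`` uses the ``999`` stop marker, ``precision=0.001`` the
    ``-9999`` marker. The default picks 0.01 mm unless a width of 9.99 mm or
    more would collide with the 999 stop marker, in which case the whole file
    is written in the 0.001 mm dialect.
    """
    if precision is None:
        wide = any(np.any(s.widths >= 9.985) for s in series)
        precision = 0.001 if wide else 0.01
    if precision == 0.01:
        stop = 999
    elif precision == 0.001:
        stop = -9999
    else:
        raise ValueError("precision must be 0.01 or 0.001 mm")
    with open(path, "w") as fh:
        for s in series:
            code = s.tree_code[:8]
            vals = np.round(s.widths / precision).astype(int)
            if stop == 999 and np.any(vals >= 999):
                raise ValueError(
                    f"tree {s.tree_code}: width too large for the 0.01 mm dialect"
                )
            year = s.first_year
            i = 0
            items = list(vals) + [stop]
            while i < len(items):
                # rows break at decade boundaries, as in classic Tucson files
                row_year = year + i
                n_in_row = 10 - (row_year % 10) if i < len(vals) else 1
                chunk = items[i : i + n_in_row]
                fh.write(f"{code:<8}{row_year:>4}" + "".join(f"{v:>6}" for v in chunk) + "\n")
                i += len(chunk)


# ---------------------------------------------------------------------------
# Basal area increment conversion
# ---------------------------------------------------------------------------

def rings_to_bai(series: RingSeries) -> pd.DataFrame:
    """Convert one ring series to annual basal area increments (mm^2/yr).

    Outside-in reconstruction anchored on the sampled DBH: the youngest
    reconstructed radius is ``dbh/2`` and earlier radii are obtained by
    subtracting ring widths, so ``BAI_t = pi (R_t^2 - R_{t-1}^2)``.
    """
    radius_inner = series.dbh_mm / 2.0 - float(series.widths.sum())
    radii = radius_inner + np.concatenate([[0.0], np.cumsum(series.widths)])
    if radius_inner < -1e-9:
        raise DataInconsistencyError(
            f"tree {series.tree_code}: reconstructed radius below zero "
            f"(dbh {series.dbh_mm} mm too small for the ring widths)"
        )
    radii = np.clip(radii, 0.0, None)
    bai = math.pi * np.diff(radii**2)
    return pd.DataFrame(
        {
            "site_id": series.site_id,
            "tree_code": series.tree_code,
            "year": series.years,
            "bai": bai,
            "radius_prev": radii[:-1],
        }
    )


def attach_previous_ba(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``ba_prev``, the basal area at the start of each ring year (mm^2).

    Requires consecutive years within each tree; the first ring of a tree gets
    the pre-first-ring disc area (zero when the pith was reached).
    """
    out = table.sort_values(["tree_code", "year"]).reset_index(drop=True)
    for code, grp in out.groupby("tree_code", sort=False):
        yrs = grp["year"].to_numpy()
        if len(yrs) > 1 and not np.all(np.diff(yrs) == 1):
            raise ValueError(f"tree {code}: gap years in BAI table; series must be continuous")
    out["ba_prev"] = math.pi * out["radius_prev"] ** 2
    return out.drop(columns=["radius_prev"])


def network_bai_table(series: list[RingSeries]) -> pd.DataFrame:
    """BAI table (site_id, tree_code, year, bai, ba_prev) for a whole network."""
    parts = [rings_to_bai(s) for s in series]
    return attach_previous_ba(pd.concat(parts, ignore_index=True))
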