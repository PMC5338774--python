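"""Summary statistics for usability-questionnaire ratings.

Ratings are on a six-point Likert scale (1 = lowest consent, 6 = highest).
For every item the summary reports

* the arithmetic mean, and
* the standard error of the mean computed from the *population* standard
  deviation: sem = sd_pop / sqrt(n) with sd_pop dividing by n (not n-1),

both rounded half-up to two decimals.  Note the published summary table this
package ships as a fixture labels the mean column "Median" — every printed
value matches the arithmetic mean, not the median, so the mean is what is
reproduced here.  Two fixture rows (Q7, Q8) print 0.81 where the computed
sem is 0.8165 (rounds to 0.82); these look truncated rather than rounded and
are kept as documented inconsistencies, not silently matched.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from math import sqrt
from pathlib import Path
from typing import Mapping, Sequence

from .errors import FormatError, ParameterError

__all__ = ["LikertSummary", "likert_summary", "load_ratings", "bundled_ratings_path"]

SCALE = (1, 6)


@dataclass(frozen=True)
class LikertSummary:
    item: str
    mean: float
    sem: float
    n: int


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def likert_summary(table: Mapping[str, Sequence[int]]) -> dict[str, LikertSummary]:
    """Per-item (mean, sem) of integer ratings in [1, 6], rounded half-up to
    2 decimals.  Items keep their input order."""
    out: dict[str, LikertSummary] = {}
    for item, ratings in table.items():
        if len(ratings) == 0:
            raise ParameterError(f"item {item!r} has no ratings")
        vals = [int(r) for r in ratings]
        if any(not SCALE[0] <= v <= SCALE[1] for v in vals):
            raise ParameterError(f"item {item!r}: ratings must lie in [1, 6]")
        n = len(vals)
        mean = sum(vals) / n
        sd_pop = sqrt(sum((v - mean) ** 2 for v in vals) / n)
        out[item] = LikertSummary(item, _round2(mean), _round2(sd_pop / sqrt(n)), n)
    return out


def load_ratings(path: str | Path) -> dict[str, list[int]]:
    """Read long-format ratings CSV with header ``item,rating``."""
    path = Path(path)
    table: dict[str, list[int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header] != ["item", "rating"]:
            raise FormatError(f"{path}: expected header 'item,rating'")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            if len(row) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 fields")
            try:
                table.setdefault(row[0].strip(), []).append(int(row[1]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if not table:
        raise FormatError(f"{path}: no ratings found")
    return table


def bundled_ratings_path() -> Path:
    """Path of the questionnaire fixture shipped with the package
    (three raters, items Q1–Q11)."""
    return Path(resources.files("cranioplan") / "data" / "questionnaire_ratings.csv")
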