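"""Permanent-emigration accounting and the corrected ("true") survival.

Apparent survival from a single-colony resighting design confounds death
with permanent emigration to other breeding sites.  Birds that were never
recorded again at the colony after their first winter sighting, but were
later seen in spring or summer (March-July) en route to or at breeding
sites elsewhere, are counted as possible permanent-emigration cases; the
per-region case fraction gives a deterministic correction

    true survival ~= apparent survival / (1 - emigration fraction).

The reported percentage divides cases by the total number of individuals in
the region (the definition that reproduces the published counts); dividing
by the number never seen again is available as an alternative denominator.
"""

from __future__ import annotations

import pandas as pd

from .encounter import Dataset, REGION_LABELS, Resighting

__all__ = [
    "count_emigration_cases",
    "emigration_rate",
    "corrected_survival",
]

AWAY_MONTHS = (3, 4, 5, 6, 7)


def emigration_rate(cases: int, total: int) -> tuple[int, float]:
    """(whole-percent for reporting, unrounded fraction for correction)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= cases <= total:
        raise ValueError("cases must lie in [0, total]")
    frac = cases / total
    return int(round(100.0 * frac)), frac


def count_emigration_cases(
    dataset: Dataset,
    away_resightings: list[Resighting],
    denominator: str = "total",
) -> pd.DataFrame:
    """Per-region emigration table.

    Columns: total individuals, number never recorded again at the colony
    after the first winter sighting, possible permanent-emigration cases
    (never-seen-again birds with at least one March-July away resighting
    after entry), reported percentage and unrounded fraction.
    """
    if denominator not in ("total", "never_seen"):
        raise ValueError("denominator must be 'total' or 'never_seen'")
    away: dict[str, list[Resighting]] = {}
    for rs in away_resightings:
        away.setdefault(rs.individual_id, []).append(rs)

    rows = []
    present = {h.region.label for h in dataset.histories}
    for label in REGION_LABELS:
        if label not in present:
            continue
        hs = [h for h in dataset.histories if h.region.label == label]
        total = len(hs)
        never = [h for h in hs if not h.detections.any()]
        cases = 0
        for h in never:
            for rs in away.get(h.id, []):
                if rs.month in AWAY_MONTHS and rs.year >= h.entry_winter + 1:
                    cases += 1
                    break
        denom = total if denominator == "total" else max(len(never), 1)
        pct, frac = emigration_rate(cases, denom) if denom else (0, 0.0)
        rows.append((label, total, len(never), cases, pct, frac))
    return pd.DataFrame(
        rows,
        columns=["region", "total", "never_seen", "cases", "percent", "fraction"],
    )


def corrected_survival(
    phi_apparent: float, emigration_fraction: float
) -> tuple[float, bool]:
    """True-survival approximation phi / (1 - fraction), capped at 1.

    Returns (value, capped flag).  Monotone increasing in both arguments and
    equal to the apparent value when the fraction is zero.
    """
    if not 0.0 <= phi_apparent <= 1.0:
        raise ValueError("phi_apparent must lie in [0, 1]")
    if not 0.0 <= emigration_fraction < 1.0:
        raise ValueError("emigration fraction must lie in [0, 1)")
    value = phi_apparent / (1.0 - emigration_fraction)
    if value > 1.0:
        return 1.0, True
    return float(value), False
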