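"""Insertion dating from the divergence between an element's two LTRs.

The two LTRs are identical at insertion and diverge independently under a
molecular clock, so the insertion time is T = K/(2r) with K the corrected
per-site divergence between them and r the substitution rate per site per
year (default 1.3e-8).  The default correction is the Jukes–Cantor closed
form K = -(3/4) ln(1 - 4p/3); the raw p-distance is available for
sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import divergence as _aligned_divergence

JC_MAX_P = 0.75  # JC correction diverges as p -> 3/4


class UndatableError(ValueError):
    """Raised when an element cannot be dated (too few aligned sites or
    divergence outside the validity range of the correction)."""


@dataclass(frozen=True)
class ClockConfig:
    rate: float = 1.3e-8  # substitutions per site per year
    correction: str = "jukes_cantor"  # jukes_cantor | raw_p
    min_aligned_sites: int = 50

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.correction not in ("jukes_cantor", "raw_p"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class InsertionDate:
    element_id: str
    p: float  # observed proportion of mismatched aligned sites
    K: float  # corrected divergence per site
    T: float  # years
    aligned_sites: int
    datable: bool = True
    family_id: str = ""


def ltr_pair_divergence(
    ltr5: str, ltr3: str, min_aligned_sites: int = 50
) -> tuple[float, int]:
    """Observed p-distance between the two LTRs over gap-free aligned columns
    of a global free-end-gap alignment."""
    if min(len(ltr5), len(ltr3)) < min_aligned_sites:
        raise UndatableError(
            f"LTR shorter than min_aligned_sites ({min_aligned_sites})"
        )
    p, aligned_sites = _aligned_divergence(ltr5, ltr3)
    if aligned_sites < min_aligned_sites:
        raise UndatableError(
            f"only {aligned_sites} aligned sites (< {min_aligned_sites})"
        )
    return p, aligned_sites


def correct_divergence(p: float, correction: str = "jukes_cantor") -> float:
    """Corrected per-site divergence K; K >= p always."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if correction == "raw_p":
        return p
    if correction == "jukes_cantor":
        if p >= JC_MAX_P:
            raise UndatableError(f"p = {p:.4f} >= 3/4: JC correction undefined")
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    raise ValueError(f"unknown correction {correction!r}")


def insertion_time(K: float, config: ClockConfig | None = None) -> float:
    """T = K/(2r) in years."""
    config = config or ClockConfig()
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / (2.0 * config.rate)


def date_element(
    element_id: str,
    ltr5: str,
    ltr3: str,
    config: ClockConfig | None = None,
    family_id: str = "",
) -> InsertionDate:
    """Full dating of one element; undatable elements come back flagged."""
    config = config or ClockConfig()
    try:
        p, aligned_sites = ltr_pair_divergence(ltr5, ltr3, config.min_aligned_sites)
        K = correct_divergence(p, config.correction)
    except UndatableError:
        return InsertionDate(
            element_id=element_id, p=float("nan"), K=float("nan"),
            T=float("nan"), aligned_sites=0, datable=False, family_id=family_id,
        )
    return InsertionDate(
        element_id=element_id,
        p=p,
        K=K,
        T=insertion_time(K, config),
        aligned_sites=aligned_sites,
        family_id=family_id,
    )


def date_elements(
    elements: Iterable,
    genome: str,
    config: ClockConfig | None = None,
    family_of: Mapping[str, str] | None = None,
) -> list[InsertionDate]:
    """Date detected elements (with sequence access via the genome string).

    Elements lacking a TSD are excluded: without the duplication there is no
    evidence the candidate is a genuine insertion.
    """
    config = config or ClockConfig()
    out = []
    for el in elements:
        if not el.tsd:
            continue
        out.append(
            date_element(
                el.element_id,
                genome[slice(*el.ltr5)],
                genome[slice(*el.ltr3)],
                config,
                family_id=(family_of or {}).get(el.element_id, ""),
            )
        )
    return out


def summarize_family_ages(
    ages_by_family: Mapping[str, Sequence[float]],
    display_cap: float | None = None,
) -> dict[str, dict[str, float]]:
    """Per-family age summary: mean, 5/25/75/95% quantiles (linear
    interpolation), min, max, n.

    ``display_cap`` optionally caps the *reported* quantiles/min/max/mean at a
    horizon (e.g. 5 MY for display); stored ages are never modified.
    """
    out = {}
    for family, ages in ages_by_family.items():
        values = np.asarray([a for a in ages if not math.isnan(a)], dtype=float)
        if len(values) == 0:
            continue
        if display_cap is not None:
            values = np.minimum(values, display_cap)
        q5, q25, q75, q95 = np.quantile(values, [0.05, 0.25, 0.75, 0.95])
        out[family] = {
            "mean": float(values.mean()),
            "q5": float(q5),
            "q25": float(q25),
            "q75": float(q75),
            "q95": float(q95),
            "min": float(values.min()),
            "max": float(values.max()),
            "n": int(len(values)),
        }
    return out
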