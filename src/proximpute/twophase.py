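"""Phase-II (validation) sampling and two-phase dataset assembly.

In a two-phase design the error-prone measure X* is available for every
unit, while the accurate measure X is collected only for a chosen subset
("queried" units).  Because the queried subset is selected by design —
independently of X — the resulting missingness in X is missing at random
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Design", "nearest_int", "sample_phase2", "assemble"]


def nearest_int(value: float) -> int:
    """Nearest integer, rounding halves to even."""
    return int(np.rint(value))


@dataclass
class Design:
    """Phase-II sampling design.

    kind = "simple_random": draw round(N q) units uniformly without
    replacement.  kind = "stratified": draw ``per_stratum`` units from
    every stratum (e.g., four tracts per county).
    """

    kind: str = "simple_random"
    q: float = 0.1
    per_stratum: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("simple_random", "stratified"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.kind == "simple_random" and not 0 < self.q <= 1:
            raise ValueError("q must be in (0, 1]")
        if self.kind == "stratified" and self.per_stratum < 1:
            raise ValueError("per_stratum must be >= 1")


def sample_phase2(
    units,
    design: Design,
    rng: np.random.Generator,
    strata=None,
) -> np.ndarray:
    """Boolean queried flags for the Phase-II subset.

    Parameters
    ----------
    units : int N, or a sequence whose length is N.
    design : the sampling design.
    rng : random generator.
    strata : per-unit stratum labels; required for stratified designs.
    """
    n = units if isinstance(units, (int, np.integer)) else len(units)
    flags = np.zeros(n, dtype=bool)
    if design.kind == "simple_random":
        k = nearest_int(n * design.q)
        idx = rng.choice(n, size=k, replace=False)
        flags[idx] = True
        return flags
    if strata is None:
        raise ValueError("stratified design requires per-unit strata labels")
    strata = np.asarray(strata)
    if len(strata) != n:
        raise ValueError("strata length must match unit count")
    for s in pd.unique(strata):
        members = np.flatnonzero(strata == s)
        if len(members) < design.per_stratum:
            raise ValueError(
                f"stratum {s!r} has {len(members)} units, fewer than the "
                f"{design.per_stratum} requested"
            )
        idx = rng.choice(members, size=design.per_stratum, replace=False)
        flags[idx] = True
    return flags


def assemble(
    x: np.ndarray,
    x_star: np.ndarray,
    queried: np.ndarray,
    **outcome_fields,
) -> pd.DataFrame:
    """Assemble the two-phase dataset, masking X where unqueried.

    ``x`` is set to NaN for unqueried units; ``x_star`` is kept for all.
    Extra keyword arrays (pop, y, z, stratum, ...) become columns.
    """
    x = np.asarray(x, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    queried = np.asarray(queried, dtype=bool)
    n = len(x)
    for name, arr in [("x_star", x_star), ("queried", queried)] + list(
        outcome_fields.items()
    ):
        if len(arr) != n:
            raise ValueError(f"column {name!r} has length {len(arr)}, expected {n}")
    masked = np.where(queried, x, np.nan)
    data = {"x": masked, "x_star": x_star, "queried": queried}
    data.update(outcome_fields)
    return pd.DataFrame(data)
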