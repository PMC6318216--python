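"""Domain types for destructively sampled trees.

A sampled tree carries its stem volume (m³) and oven-dry masses (kg) of the
stem, branch and foliage components.  Crown (branches + foliage) and
aboveground biomass (stem + crown) are always derived, never stored
independently, so component additivity holds by construction.

Masses are kept in kilograms at the file boundary; every analysis routine
consumes megagrams (Mg), so that fitted biomass conversion and expansion
factors come out in Mg per m³ of stem volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COMPONENTS = ("stem", "branches", "foliage", "crown", "agb")

#: Number of equal-length stem segments in the sectional volume protocol.
N_SEGMENTS = 5


def to_mg(mass_kg: float) -> float:
    """Convert a mass from kilograms to megagrams (tonnes)."""
    return mass_kg / 1000.0


@dataclass(frozen=True)
class StemSegment:
    """One of the five equal-length stem segments.

    ``mid_diameter`` is measured at the segment midpoint (cm); ``length`` in
    metres.  Fresh and disc masses (kg) are optional and only needed when the
    segment dry mass is to be derived from the disc moisture ratio.
    """

    length: float
    mid_diameter: float
    fresh_mass: float | None = None
    disc_fresh_mass: float | None = None
    disc_dry_mass: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment length must be > 0, got {self.length}")
        if self.mid_diameter <= 0:
            raise ValueError(
                f"segment mid-diameter must be > 0, got {self.mid_diameter}"
            )
        if self.fresh_mass is not None and self.fresh_mass < 0:
            raise ValueError("segment fresh mass must be >= 0")
        if self.disc_fresh_mass is not None and self.disc_fresh_mass <= 0:
            raise ValueError("disc fresh mass must be > 0")
        if self.disc_dry_mass is not None and self.disc_dry_mass <= 0:
            raise ValueError("disc dry mass must be > 0")
        if (
            self.disc_dry_mass is not None
            and self.disc_fresh_mass is not None
            and self.disc_dry_mass > self.disc_fresh_mass
        ):
            raise ValueError(
                "disc dry mass exceeds disc fresh mass "
                f"({self.disc_dry_mass} > {self.disc_fresh_mass})"
            )

    def dry_mass(self) -> float:
        """Segment dry mass (kg) via the disc oven-dry/fresh ratio."""
        if self.fresh_mass is None or self.disc_fresh_mass is None or self.disc_dry_mass is None:
            raise ValueError("segment lacks the masses needed to derive dry mass")
        return segment_dry_mass(self.fresh_mass, self.disc_fresh_mass, self.disc_dry_mass)


def segment_dry_mass(fresh_mass: float, disc_fresh: float, disc_dry: float) -> float:
    """Dry mass (kg) of a stem segment, branch or foliage lot.

    The oven-dry-to-fresh mass ratio of the sampled disc scales the field
    fresh mass of the whole piece.
    """
    if disc_fresh <= 0:
        raise ValueError("disc fresh mass must be > 0")
    if disc_dry < 0 or disc_dry > disc_fresh:
        raise ValueError(
            f"impossible moisture ratio: disc dry {disc_dry} kg vs fresh {disc_fresh} kg"
        )
    if fresh_mass < 0:
        raise ValueError("fresh mass must be >= 0")
    return fresh_mass * (disc_dry / disc_fresh)


def hohenadl_volume(segments: Sequence[StemSegment], rel_tol: float = 1e-6) -> float:
    """Sectional stem volume (m³) from five equal-length segments.

    Each segment contributes its mid-point cross-sectional area times its
    length: V = Σ (π/4)·(dᵢ/100)²·Lᵢ.  The stump is excluded from the stem,
    so the five segments span the felled stem only.
    """
    segments = list(segments)
    if len(segments) != N_SEGMENTS:
        raise ValueError(
            f"sectional volume needs exactly {N_SEGMENTS} segments, got {len(segments)}"
        )
    lengths = np.array([s.length for s in segments], dtype=float)
    ref = lengths.mean()
    if np.any(np.abs(lengths - ref) > rel_tol * ref):
        raise ValueError(f"segment lengths are not equal within tolerance: {lengths.tolist()}")
    diam_m = np.array([s.mid_diameter for s in segments], dtype=float) / 100.0
    volume = float(np.sum(math.pi / 4.0 * diam_m**2 * lengths))
    if volume <= 0:
        raise ValueError("computed stem volume is not positive")
    return volume


@dataclass
class TreeRecord:
    """One destructively sampled tree.

    Component dry masses are in kg; ``stem_volume`` in m³ (given directly or
    derived from the five stem segments).  ``foliage_absent`` marks trees
    sampled leaf-off whose foliage mass is recorded as 0 rather than missing,
    which keeps crown = branches + foliage additive.
    """

    species: str
    dbh: float
    height: float
    stem_volume: float | None
    w_stem: float
    w_branches: float
    w_foliage: float = 0.0
    foliage_absent: bool = False
    tree_id: str | None = None
    segments: list[StemSegment] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dbh <= 0:
            raise ValueError(f"dbh must be > 0, got {self.dbh}")
        if self.height <= 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        for name in ("w_stem", "w_branches", "w_foliage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.stem_volume is None and self.segments is not None:
            self.stem_volume = hohenadl_volume(self.segments)
        if self.stem_volume is not None and self.stem_volume <= 0:
            raise ValueError(f"stem volume must be > 0, got {self.stem_volume}")

    @property
    def w_crown(self) -> float:
        return self.w_branches + self.w_foliage

    @property
    def w_agb(self) -> float:
        return self.w_stem + self.w_crown

    def component_mass(self, component: str) -> float:
        """Dry mass (kg) of one of stem/branches/foliage/crown/agb."""
        if component not in COMPONENTS:
            raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")
        return {
            "stem": self.w_stem,
            "branches": self.w_branches,
            "foliage": self.w_foliage,
            "crown": self.w_crown,
            "agb": self.w_agb,
        }[component]


@dataclass
class Dataset:
    """A collection of tree records, optionally with a row-rejection report."""

    records: list[TreeRecord]
    rejected: list[tuple[int, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def subset(self, species: str) -> "Dataset":
        return Dataset([r for r in self.records if r.species == species])

    def component_arrays(self, component: str, species: str | None = None):
        """(W, V) arrays for fitting: W in Mg, V in m³.

        Only records with a positive stem volume enter; a BCEF is undefined
        without one.
        """
        recs = self.records if species is None else [r for r in self.records if r.species == species]
        recs = [r for r in recs if r.stem_volume is not None and r.stem_volume > 0]
        W = np.array([to_mg(r.component_mass(component)) for r in recs], dtype=float)
        V = np.array([r.stem_volume for r in recs], dtype=float)
        return W, V

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "tree_id": r.tree_id,
                    "species": r.species,
                    "dbh_cm": r.dbh,
                    "height_m": r.height,
                    "volume_m3": r.stem_volume,
                    "stem_kg": r.w_stem,
                    "branches_kg": r.w_branches,
                    "foliage_kg": r.w_foliage,
                    "crown_kg": r.w_crown,
                    "agb_kg": r.w_agb,
                    "foliage_absent": r.foliage_absent,
                }
            )
        return pd.DataFrame(rows)

    def analysis_pairs(self, components: Iterable[str] = COMPONENTS) -> pd.DataFrame:
        """Long-format analysis-ready (species, component, W_Mg, V_m3) table."""
        rows = []
        for comp in components:
            for r in self.records:
                if r.stem_volume is None or r.stem_volume <= 0:
                    continue
                rows.append(
                    {
                        "species": r.species,
                        "component": comp,
                        "W_Mg": to_mg(r.component_mass(comp)),
                        "V_m3": r.stem_volume,
                    }
                )
        return pd.DataFrame(rows)
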