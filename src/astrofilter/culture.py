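"""Synthetic 2D cultures emulating imaged fields of neuron-astrocyte cultures.

Cell bodies are laid out as a hard-core (Matern-II-style rejection) Poisson
point process in a rectangular field: candidate positions are drawn uniformly
at Poisson-distributed count and accepted only if they keep a minimum
inter-soma distance.  Each accepted cell is independently assigned a class
(astrocyte / neuron / unclassified, where "unclassified" stands for cells
without usable Ca2+ activity, including unresponsive astrocytes) and
astrocytes are independently flagged as directly stimulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["CellRecord", "CultureSpec", "Culture", "generate_culture",
           "DEFAULT_SPEC", "PackingError"]

CELL_CLASSES = ("astrocyte", "neuron", "unclassified")


class PackingError(RuntimeError):
    """Hard-core radius too large for the requested density."""


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    x_um: float
    y_um: float
    cell_class: str
    stimulated: bool

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.stimulated and self.cell_class != "astrocyte":
            raise ValueError("only astrocytes may be stimulated")


@dataclass(frozen=True)
class CultureSpec:
    """Statistical description of one synthetic field of view.

    ``cell_density`` is in cells/mm^2; ``class_fractions`` is
    (astrocyte, neuron, unclassified) and must sum to 1;
    ``stimulated_fraction`` applies to astrocytes only.
    """

    field_width_um: float = 500.0
    field_height_um: float = 500.0
    cell_density_mm2: float = 800.0
    class_fractions: tuple[float, float, float] = (0.25, 0.45, 0.30)
    stimulated_fraction: float = 0.5
    hard_core_radius_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.class_fractions
        if len(fr) != 3 or any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1) > 1e-9:
            raise ValueError("class_fractions must be three probabilities summing to 1")
        if not 0 <= self.stimulated_fraction <= 1:
            raise ValueError("stimulated_fraction must lie in [0, 1]")
        if self.cell_density_mm2 <= 0 or self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("density and field dimensions must be > 0")
        if self.hard_core_radius_um < 0:
            raise ValueError("hard_core_radius_um must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CultureSpec":
        d = json.loads(Path(path).read_text())
        d["class_fractions"] = tuple(d["class_fractions"])
        return cls(**d)


@dataclass(frozen=True)
class Culture:
    """A realised field of cells."""

    cells: tuple[CellRecord, ...]
    spec: CultureSpec | None = None

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def positions(self) -> np.ndarray:
        return np.array([(c.x_um, c.y_um) for c in self.cells], dtype=float).reshape(-1, 2)

    def by_class(self, cell_class: str) -> tuple[CellRecord, ...]:
        return tuple(c for c in self.cells if c.cell_class == cell_class)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "x_um": [c.x_um for c in self.cells],
                "y_um": [c.y_um for c in self.cells],
                "cell_class": [c.cell_class for c in self.cells],
                "stimulated": [c.stimulated for c in self.cells],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spec: CultureSpec | None = None) -> "Culture":
        cells = tuple(
            CellRecord(int(r.cell_id), float(r.x_um), float(r.y_um),
                       str(r.cell_class), bool(r.stimulated))
            for r in df.itertuples()
        )
        return cls(cells, spec)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Culture":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


DEFAULT_SPEC = CultureSpec()


def _sample_hard_core(n_target: int, width: float, height: float, radius: float,
                      rng: np.random.Generator, max_attempts: int) -> np.ndarray:
    """Sequential dart throwing with a minimum-distance constraint.

    Raises :class:`PackingError` once the rejection budget is exhausted,
    which happens when the requested radius cannot be packed at the
    requested density.
    """
    if n_target == 0:
        return np.empty((0, 2))
    if radius == 0:
        return np.column_stack([rng.uniform(0, width, n_target),
                                rng.uniform(0, height, n_target)])
    accepted: list[np.ndarray] = []
    tree: cKDTree | None = None
    attempts = 0
    while len(accepted) < n_target:
        p = np.array([rng.uniform(0, width), rng.uniform(0, height)])
        attempts += 1
        if tree is None or not tree.query_ball_point(p, radius):
            accepted.append(p)
            tree = cKDTree(np.asarray(accepted))
        elif attempts > max_attempts:
            raise PackingError(
                f"hard-core radius {radius} um infeasible at this density: "
                f"{len(accepted)}/{n_target} cells placed in {attempts} attempts"
            )
    return np.asarray(accepted)


def generate_culture(spec: CultureSpec, max_reject_factor: float = 30.0) -> Culture:
    """Draw one synthetic culture; bitwise reproducible given ``spec.seed``.

    The cell count is Poisson(density * area); positions are drawn by
    sequential rejection so that no two somata come closer than the
    hard-core radius.  An explicit :class:`PackingError` is raised if the
    requested radius cannot be packed at the requested density.
    """
    rng = np.random.default_rng(spec.seed)
    area_mm2 = spec.field_width_um * spec.field_height_um * 1e-6
    n_target = rng.poisson(spec.cell_density_mm2 * area_mm2)
    max_attempts = int(max_reject_factor * max(n_target, 1))
    pts = _sample_hard_core(n_target, spec.field_width_um, spec.field_height_um,
                            spec.hard_core_radius_um, rng, max_attempts)

    n = pts.shape[0]
    classes = rng.choice(len(CELL_CLASSES), size=n, p=list(spec.class_fractions))
    stim_draw = rng.uniform(size=n) < spec.stimulated_fraction
    cells = tuple(
        CellRecord(
            cell_id=i,
            x_um=float(pts[i, 0]),
            y_um=float(pts[i, 1]),
            cell_class=CELL_CLASSES[classes[i]],
            stimulated=bool(stim_draw[i]) and CELL_CLASSES[classes[i]] == "astrocyte",
        )
        for i in range(n)
    )
    return Culture(cells, spec)
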