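"""Planted-module binary matrices with known ground truth.

The default configuration emulates the meta-GSA benchmark: a 400 x 400
binary matrix (400 gene sets x 400 pairwise tests) carrying seven
partially overlapping modules of highly variable shape, within-module
signal gradients, and 10% random background noise.  Module M1 is "tall"
(25 phenotypes x 250 gene sets, a proliferation-like process); the
others are "wide"; M1's gene sets overlap every module except M3; M2's
phenotypes overlap M4-M7; M6 overlaps M1 in both dimensions.  Within
each module the per-row signal decays linearly from ``signal_start``
(first gene set) to ``signal_end`` (last), so early rows are strongly
associated and late rows only weakly — emulating real GSA signal decay.

Background noise only *adds* associations outside module blocks; the
gradient only *removes* them inside blocks.  The two mechanisms are
orthogonal, so within-block density is governed by the gradient alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AssociationMatrix

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_modules",
    "apply_signal_gradient",
    "add_background_noise",
    "make_artificial",
]


@dataclass(frozen=True)
class ModuleSpec:
    """Placement and signal gradient of one planted module.

    ``col_segments`` lists (anchor, width) pairs, allowing a module's
    phenotypes to occupy disjoint column stretches (needed for modules
    that overlap two others in columns).
    """

    name: str
    row_anchor: int
    n_rows: int
    col_segments: tuple[tuple[int, int], ...]
    signal_start: float
    signal_end: float

    def __post_init__(self) -> None:
        if not 0.0 < self.signal_end <= self.signal_start <= 1.0:
            raise ValueError(
                f"{self.name}: need 0 < signal_end <= signal_start <= 1, "
                f"got {self.signal_start}..{self.signal_end}"
            )
        if self.n_rows < 1 or not self.col_segments:
            raise ValueError(f"{self.name}: empty module block")

    @property
    def rows(self) -> np.ndarray:
        return np.arange(self.row_anchor, self.row_anchor + self.n_rows)

    @property
    def cols(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(a, a + w) for a, w in self.col_segments]
        )

    @property
    def n_cols(self) -> int:
        return int(sum(w for _, w in self.col_segments))


def default_modules() -> list[ModuleSpec]:
    """The seven-module benchmark layout.

    Gradients follow the benchmark definition — M1 90-40%, M2 80-50%,
    M3 80-40%, M4 90-50%, M5 80-40%, M6 90-40%, M7 60-50%.  M1 is tall
    (25 x 250); M2 is the widest (120 phenotypes); M7 is wide but weak
    (its gradient barely clears the 50% gate); M6 is the smallest and
    overlaps M1 in both dimensions and M2 in columns.
    """
    return [
        ModuleSpec("M1", 0, 250, ((0, 25),), 0.90, 0.40),
        ModuleSpec("M2", 230, 40, ((50, 120),), 0.80, 0.50),
        ModuleSpec("M3", 330, 60, ((200, 40),), 0.80, 0.40),
        ModuleSpec("M4", 60, 40, ((150, 40),), 0.90, 0.50),
        ModuleSpec("M5", 120, 40, ((60, 40),), 0.80, 0.40),
        ModuleSpec("M6", 185, 30, ((15, 10), (160, 10)), 0.90, 0.40),
        ModuleSpec("M7", 0, 60, ((130, 100),), 0.60, 0.50),
    ]


@dataclass
class SimulationConfig:
    n_rows: int = 400
    n_cols: int = 400
    background_noise: float = 0.10
    modules: list[ModuleSpec] = field(default_factory=default_modules)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_noise <= 1.0:
            raise ValueError("background_noise must be a fraction")
        for spec in self.modules:
            if spec.row_anchor + spec.n_rows > self.n_rows:
                raise ValueError(f"{spec.name}: rows exceed matrix bounds")
            if spec.cols.max(initial=-1) >= self.n_cols or spec.cols.min(initial=0) < 0:
                raise ValueError(f"{spec.name}: columns exceed matrix bounds")


@dataclass
class GroundTruth:
    """Planted row/column membership per module."""

    modules: dict[str, dict[str, np.ndarray]]

    def names(self) -> list[str]:
        return list(self.modules)

    def cols(self, name: str) -> set[int]:
        return set(self.modules[name]["cols"].tolist())

    def rows(self, name: str) -> set[int]:
        return set(self.modules[name]["rows"].tolist())

    def to_jsonable(self) -> dict:
        return {
            name: {"rows": mod["rows"].tolist(), "cols": mod["cols"].tolist()}
            for name, mod in self.modules.items()
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "GroundTruth":
        return cls(
            {
                name: {
                    "rows": np.asarray(mod["rows"], dtype=np.intp),
                    "cols": np.asarray(mod["cols"], dtype=np.intp),
                }
                for name, mod in obj.items()
            }
        )


def apply_signal_gradient(
    block: np.ndarray, start: float, end: float, rng: np.random.Generator
) -> np.ndarray:
    """Degrade a filled block row by row (only 1 -> 0 replacements).

    Row r (r = 0 .. R-1) keeps each association with probability
    interpolated linearly from ``start`` (first row) to ``end`` (last).
    """
    if not 0.0 < end <= start <= 1.0:
        raise ValueError("need 0 < end <= start <= 1")
    block = np.asarray(block, dtype=np.int8)
    R = block.shape[0]
    keep_p = np.linspace(start, end, num=R) if R > 1 else np.array([start])
    keep = rng.random(block.shape) < keep_p[:, None]
    return (block & keep).astype(np.int8)


def add_background_noise(
    matrix: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    module_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Set background (non-module) zero cells to 1 with probability ``rate``.

    Module cells are untouched.  Rates above 0.5 are outside the tested
    range and trigger a warning.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("noise rate must be a fraction")
    if rate > 0.5:
        import warnings

        warnings.warn("background noise above 50% is outside the tested range")
    matrix = np.asarray(matrix, dtype=np.int8)
    if module_mask is None:
        module_mask = np.zeros(matrix.shape, dtype=bool)
    noise = rng.random(matrix.shape) < rate
    out = matrix.copy()
    out[~module_mask & noise] = 1
    return out


def make_artificial(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[AssociationMatrix, GroundTruth]:
    """Generate one planted-module matrix and its ground truth.

    Module blocks are filled with 1s, degraded by their signal gradient
    and OR-ed into the matrix (overlapping blocks keep the union of
    their signals); background noise is then added outside all blocks.
    """
    config = config or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mat = np.zeros((config.n_rows, config.n_cols), dtype=np.int8)
    module_mask = np.zeros(mat.shape, dtype=bool)
    truth: dict[str, dict[str, np.ndarray]] = {}
    for spec in config.modules:
        rows = spec.rows
        cols = spec.cols
        block = np.ones((rows.size, cols.size), dtype=np.int8)
        block = apply_signal_gradient(block, spec.signal_start, spec.signal_end, rng)
        mat[np.ix_(rows, cols)] |= block
        module_mask[np.ix_(rows, cols)] = True
        truth[spec.name] = {"rows": rows.copy(), "cols": cols.copy()}
    mat = add_background_noise(mat, config.background_noise, rng, module_mask)
    matrix = AssociationMatrix(
        values=mat,
        row_ids=[f"gs{i}" for i in range(config.n_rows)],
        col_ids=[f"ph{j}" for j in range(config.n_cols)],
    )
    return matrix, GroundTruth(truth)
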