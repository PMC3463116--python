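"""Model/results interface over the iterative bi-clustering core.

``IBBIG`` wraps a binary association matrix plus the search parameters;
``fit`` runs the full iterative extraction and returns an
``IBBIGResults`` carrying the extracted modules, their scores and
serialization/plot helpers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AssociationMatrix, GAParams
from .extract import ModuleSet, run_ibbig

__all__ = ["IBBIG", "IBBIGResults"]


class IBBIG:
    """Iterative binary bi-clustering of a gene-set x phenotype matrix.

    Parameters
    ----------
    data
        An :class:`AssociationMatrix`, a labelled 0/1 ``DataFrame`` or a
        plain binary array (labels are generated).
    params
        :class:`GAParams`; keyword overrides may be passed directly,
        e.g. ``IBBIG(df, alpha=0.5, n_modules=8)``.
    """

    def __init__(self, data, params: GAParams | None = None, **overrides):
        if isinstance(data, AssociationMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = AssociationMatrix.from_dataframe(data)
        else:
            self.data = AssociationMatrix(values=np.asarray(data))
        base = params or GAParams()
        self.params = base.with_(**overrides) if overrides else base

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **overrides) -> "IBBIG":
        return cls(df, **overrides)

    def fit(
        self,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        stop_on_zero: bool = True,
    ) -> "IBBIGResults":
        """Run the iterative extraction; a fixed seed is bit-reproducible."""
        params = self.params if seed is None else self.params.with_(seed=seed)
        modules = run_ibbig(self.data, params, rng=rng, stop_on_zero=stop_on_zero)
        return IBBIGResults(self, modules)


class IBBIGResults:
    """Extracted modules with scores, membership calls and summaries."""

    def __init__(self, model: IBBIG, module_set: ModuleSet):
        self.model = model
        self.module_set = module_set

    @property
    def modules(self):
        return self.module_set.modules

    @property
    def n_modules(self) -> int:
        return len(self.module_set)

    def scores(self) -> np.ndarray:
        return self.module_set.scores()

    def weighted_scores(self) -> np.ndarray:
        return self.module_set.weighted_scores()

    def retained(self):
        """Modules with positive weighted score."""
        return self.module_set.retained()

    def background_score(self, seed: int | None = None) -> float:
        """Fitness the search reaches on a signal-free permutation null.

        The entries of every column of the input matrix are permuted
        independently — column margins are preserved, gene-set coherence
        is destroyed — and one module search is run on the permuted
        matrix.  The returned score is the best fitness pure noise of the
        same density can attain, i.e. the background level of the
        ranked-module fitness plot.  Cached after the first call.
        """
        if getattr(self, "_background", None) is None:
            from .core import AssociationMatrix
            from .ga import evolve_module

            base = self.model.params.seed or 0
            rng = np.random.default_rng(
                seed if seed is not None else (base + 101) % 2**31
            )
            vals = self.model.data.values.copy()
            for j in range(vals.shape[1]):
                rng.shuffle(vals[:, j])
            null = AssociationMatrix(vals)
            mod = evolve_module(null.to_weights(), self.model.params, rng)
            self._background = float(mod.score)
        return self._background

    def n_above_background(self) -> int:
        """Modules whose fitness stands clear of the permutation-null level."""
        return int((self.scores() > self.background_score()).sum())

    def module_table(self) -> pd.DataFrame:
        return self.module_set.module_table()

    def geneset_table(self) -> pd.DataFrame:
        return self.module_set.geneset_table()

    def summary(self) -> str:
        df = self.module_table()
        lines = [
            "iBBiG extraction results",
            f"  matrix: {self.model.data.n_rows} gene sets x "
            f"{self.model.data.n_cols} phenotypes",
            f"  params: alpha={self.model.params.alpha}, "
            f"P={self.model.params.pop_size}, MR={self.model.params.mutation_rate}, "
            f"SR={self.model.params.success_ratio}, SP={self.model.params.selection_pressure}, "
            f"stagnation={self.model.params.stagnation}",
            f"  modules extracted: {self.n_modules} "
            f"(positive weighted score: {len(self.retained())}, "
            f"above background: {self.n_above_background()})",
            "",
            f"{'module':<8}{'k':>5}{'score':>12}{'weighted':>10}{'genesets':>10}",
        ]
        for _, row in df.iterrows():
            lines.append(
                f"{row['module']:<8}{row['k']:>5d}{row['score']:>12.2f}"
                f"{row['weighted_score']:>10.3f}{row['n_genesets']:>10d}"
            )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write module/gene-set TSVs and a JSON run summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.module_table().to_csv(out / "modules.tsv", sep="\t", index=False)
        self.geneset_table().to_csv(out / "genesets.tsv", sep="\t", index=False)
        params = self.model.params
        summary = {
            "n_rows": self.model.data.n_rows,
            "n_cols": self.model.data.n_cols,
            "n_modules_extracted": self.n_modules,
            "n_retained": len(self.retained()),
            "n_above_background": self.n_above_background(),
            "params": {
                "alpha": params.alpha,
                "pop_size": params.pop_size,
                "mutation_rate": params.mutation_rate,
                "success_ratio": params.success_ratio,
                "selection_pressure": params.selection_pressure,
                "stagnation": params.stagnation,
                "n_modules": params.n_modules,
                "seed": params.seed,
            },
        }
        (out / "run_summary.json").write_text(json.dumps(summary, indent=1))

    def plot_scores(self, ax=None):
        """Bar plots of module fitness, size and weighted score."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(1, 3, figsize=(10, 3))
        else:
            axes = ax
        df = self.module_table()
        axes[0].bar(df["module"], df["score"])
        axes[0].set_ylabel("fitness score S")
        axes[1].bar(df["module"], df["k"])
        axes[1].set_ylabel("module size k")
        finite = df["weighted_score"].replace(-np.inf, np.nan)
        axes[2].bar(df["module"], finite)
        axes[2].axhline(0.0, color="k", lw=0.5)
        axes[2].set_ylabel("weighted score")
        for a in axes:
            a.tick_params(axis="x", rotation=90)
        return axes
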