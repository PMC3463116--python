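"""Iterative module extraction with partial signal masking.

One GA run finds a single module.  To find them all, the weight matrix
is partially masked after each discovery and the search is re-run: for
every gene set that contributed to the module's score, the fraction of
its signal that the score actually used — the homogeneity weight
``(1 - H_i)^(1 - alpha)`` — is removed from its module-column weights.
Perfectly homogeneous rows (H_i = 0) are zeroed; heterogeneous rows keep
a residue, which is what lets genuinely overlapping and weaker modules
surface in later iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AssociationMatrix,
    GAParams,
    Module,
    WeightMatrix,
    entropy,
    weighted_module_score,
)
from .ga import evolve_module

__all__ = ["ModuleSet", "update_weights", "assign_genesets", "run_ibbig"]


def update_weights(weights: WeightMatrix, module: Module, alpha: float = 0.3) -> WeightMatrix:
    """Mask the portion of the signal the module's fitness score used.

    For every scoring gene set i (``S_i > 0``) and every column j in the
    module: ``w_ij <- w_ij * (1 - (1 - H_i)^(1 - alpha))``.  All other
    entries are untouched.  The result stays in [0, 1] and is entrywise
    <= the input, so the weight matrix is non-increasing over iterations.
    """
    W = weights.values
    cols = np.asarray(module.columns, dtype=np.intp)
    if module.geneset_scores.shape[0] != W.shape[0]:
        raise ValueError("module/weight-matrix shape mismatch")
    if cols.size and (cols.min() < 0 or cols.max() >= W.shape[1]):
        raise ValueError("module/weight-matrix shape mismatch")
    out = W.copy()
    rows = np.flatnonzero(module.geneset_scores > 0)
    if rows.size and cols.size:
        p = W[np.ix_(rows, cols)].sum(axis=1) / cols.size
        used = (1.0 - entropy(p)) ** (1.0 - alpha)
        out[np.ix_(rows, cols)] *= (1.0 - used)[:, None]
    return WeightMatrix(out, list(weights.row_ids), list(weights.col_ids))


def assign_genesets(geneset_scores: np.ndarray, random_state: int = 0) -> np.ndarray:
    """Call gene-set membership from the per-row scores of one module.

    A two-component 1-D Gaussian mixture separates high-scoring gene sets
    from the background null distribution; members are the rows whose
    posterior probability of the higher-mean component exceeds 0.5.  The
    mixture is fitted on the log scores of the rows that scored at all:
    scores are products of an association count and a homogeneity weight,
    so the log is their natural Gaussian scale, and the structural zeros
    of rows below the association gate would otherwise pin the null
    component at exactly zero and make every scoring row a member.
    If no score is positive, nothing is a member; if the mixture is
    degenerate (component means indistinguishable) the call falls back to
    ``scores > 0``.
    """
    scores = np.asarray(geneset_scores, dtype=np.float64).ravel()
    members = np.zeros(scores.size, dtype=bool)
    positive = scores > 0
    if not positive.any():
        return members
    pos_vals = np.log(scores[positive])
    if np.unique(pos_vals).size < 3:  # e.g. {0, c}: trivially separable
        return positive
    from sklearn.mixture import GaussianMixture

    gmm = GaussianMixture(n_components=2, n_init=1, random_state=random_state)
    X = pos_vals[:, None]
    try:
        gmm.fit(X)
    except Exception:
        return positive
    means = gmm.means_.ravel()
    scale = max(pos_vals.max() - pos_vals.min(), 1e-12)
    if abs(means[0] - means[1]) < 1e-6 * scale:
        return positive
    high = int(np.argmax(means))
    posterior = gmm.predict_proba(X)[:, high]
    members[positive] = posterior > 0.5
    return members


@dataclass
class ModuleSet:
    """Ordered collection of extracted modules plus run provenance."""

    modules: list[Module]
    row_ids: list[str]
    col_ids: list[str]
    params: GAParams

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    def scores(self) -> np.ndarray:
        return np.array([mod.score for mod in self.modules])

    def weighted_scores(self) -> np.ndarray:
        return np.array([mod.weighted_score for mod in self.modules])

    def ranked(self) -> list[Module]:
        """Modules re-ranked by decreasing weighted score (view)."""
        return sorted(self.modules, key=lambda mod: -mod.weighted_score)

    def retained(self) -> list[Module]:
        """Modules with positive weighted score (the retention criterion)."""
        return [mod for mod in self.modules if mod.weighted_score > 0]

    def module_table(self):
        import pandas as pd

        rows = []
        for mod in self.modules:
            rows.append(
                {
                    "module": f"M{mod.iteration}",
                    "iteration": mod.iteration,
                    "k": mod.k,
                    "score": mod.score,
                    "weighted_score": mod.weighted_score,
                    "n_genesets": mod.n_members,
                    "phenotypes": ";".join(self.col_ids[c] for c in mod.columns),
                }
            )
        return pd.DataFrame(rows)

    def geneset_table(self):
        import pandas as pd

        rows = []
        for mod in self.modules:
            for i in np.flatnonzero(mod.geneset_scores > 0):
                rows.append(
                    {
                        "module": f"M{mod.iteration}",
                        "geneset": self.row_ids[i],
                        "score": float(mod.geneset_scores[i]),
                        "member": bool(mod.geneset_members[i]),
                    }
                )
        return pd.DataFrame(rows, columns=["module", "geneset", "score", "member"])


def run_ibbig(
    matrix: AssociationMatrix,
    params: GAParams | None = None,
    rng: np.random.Generator | None = None,
    stop_on_zero: bool = True,
) -> ModuleSet:
    """Extract up to ``params.n_modules`` modules from a binary matrix.

    The weight matrix starts equal to ``M``; each iteration runs the
    genetic search on the current weights, records the best module with
    its gene-set membership calls and weighted score, and masks the used
    signal.  With ``stop_on_zero`` the run ends early once a module
    scores 0 (nothing left to find); otherwise all requested iterations
    are emitted.
    """
    params = params or GAParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    weights = matrix.to_weights()
    modules: list[Module] = []
    for t in range(1, params.n_modules + 1):
        module = evolve_module(weights, params, rng)
        module.iteration = t
        if module.score <= 0.0 or module.k < 2:
            if stop_on_zero:
                break
            modules.append(module)
            continue
        module.geneset_members = assign_genesets(module.geneset_scores)
        module.weighted_score = weighted_module_score(
            module.score, module.k, matrix.n_cols
        )
        weights = update_weights(weights, module, params.alpha)
        modules.append(module)
    return ModuleSet(
        modules=modules,
        row_ids=list(matrix.row_ids),
        col_ids=list(matrix.col_ids),
        params=params,
    )
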