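"""Practical identifiability via collinearity indices.

For a weighted observable-sensitivity matrix S (rows: measurement points,
columns: parameters), normalise each column to unit Euclidean norm and, for a
parameter subset K, compute

    gamma_K = 1 / sqrt(lambda_min(S_K' S_K)),

the collinearity index.  gamma_K >= 1 always; a large value means the
parameters in K can compensate one another's effect on the observed outputs,
i.e. the subset is not identifiable in practice from these data.  Subsets
are enumerated exhaustively up to ``subset_max_size`` (default 4; cheap for
the case studies' <= 8 parameters), then grown greedily from the worst subset
up to the number of parameters.

Structural identifiability is *not* analysed numerically here: it requires a
symbolic rank test on Lie derivatives, for which users should run a dedicated
external tool before estimation and record the verdict in the run
configuration.  Offering a numeric stand-in would give false assurance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["CollinearityReport", "collinearity_indices"]

DEFAULT_THRESHOLD = 20.0


@dataclass
class CollinearityReport:
    """Collinearity indices per parameter subset, with flagged subsets."""

    indices: dict                 # {tuple of param names: gamma}
    flagged: list                 # subsets with gamma > threshold
    threshold: float
    insensitive: list = field(default_factory=list)

    @property
    def identifiable(self):
        return len(self.flagged) == 0

    def max_index(self):
        return max(self.indices.values()) if self.indices else float("nan")

    def to_dict(self):
        return {
            "threshold": self.threshold,
            "indices": {"|".join(k): v for k, v in self.indices.items()},
            "flagged": [list(k) for k in self.flagged],
            "insensitive": list(self.insensitive),
        }


def _gamma(gram, cols):
    sub = gram[np.ix_(cols, cols)]
    lam_min = float(np.linalg.eigvalsh(sub)[0])
    if lam_min <= 1e-300:
        return float("inf")
    return 1.0 / np.sqrt(lam_min)


def collinearity_indices(sensitivity_matrix, param_names=None,
                         subset_max_size=4, threshold=DEFAULT_THRESHOLD):
    """Collinearity indices of all parameter subsets of sizes 2..K_max.

    ``sensitivity_matrix`` should already carry the measurement weighting
    (rows divided by sigma).  Columns with zero norm are reported as
    insensitive and excluded.  Beyond ``subset_max_size`` the worst subset is
    grown greedily so the largest indices are still surfaced for models with
    many parameters.
    """
    S = np.asarray(sensitivity_matrix, dtype=float)
    if S.ndim != 2:
        raise ValueError("sensitivity matrix must be 2-D")
    n_rows, n_params = S.shape
    if n_rows < n_params:
        warnings.warn("fewer sensitivity rows than parameters; "
                      "indices may be degenerate", stacklevel=2)
    if param_names is None:
        param_names = tuple(f"theta_{j+1}" for j in range(n_params))
    norms = np.linalg.norm(S, axis=0)
    insensitive = [param_names[j] for j in range(n_params) if norms[j] == 0]
    if len(insensitive) == n_params:
        raise ValueError("model output insensitive to all parameters")
    if insensitive:
        warnings.warn(f"insensitive parameters excluded: {insensitive}",
                      stacklevel=2)
    active = [j for j in range(n_params) if norms[j] > 0]
    Shat = S[:, active] / norms[active]
    gram = Shat.T @ Shat
    names = [param_names[j] for j in active]

    indices = {}
    k_cap = min(subset_max_size, len(active))
    for k in range(2, k_cap + 1):
        for cols in combinations(range(len(active)), k):
            indices[tuple(names[c] for c in cols)] = _gamma(gram, list(cols))
    # greedy growth beyond the exhaustive cap
    if len(active) > k_cap and indices:
        worst = max((k for k in indices if len(k) == k_cap),
                    key=lambda k: indices[k])
        current = [names.index(nm) for nm in worst]
        while len(current) < len(active):
            best_add, best_gamma = None, -np.inf
            for j in range(len(active)):
                if j in current:
                    continue
                g = _gamma(gram, current + [j])
                if g > best_gamma:
                    best_add, best_gamma = j, g
            current.append(best_add)
            indices[tuple(names[c] for c in current)] = best_gamma
    flagged = [k for k, g in indices.items() if g > threshold]
    return CollinearityReport(indices=indices, flagged=flagged,
                              threshold=threshold, insensitive=insensitive)
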