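"""Candidate-effect universe and exhaustive enumeration of hierarchical models.

The analysis compares every regression model that can be formed from a fixed
set of candidate effects: main effects plus a small number of two-way
interactions.  A model is *hierarchical* (respects marginality) when every
included interaction has both of its parent main effects included; models
violating this are mis-specified and excluded, as is the empty
intercept-only model.

With the default candidate set — 13 main effects and 2 interactions sharing
one parent (age of the youngest child) — the 2^15 = 32,768 raw subsets
reduce to exactly 13,311 valid models:
2^13 (no interaction) + 2 * 2^11 (one interaction, its 2 parents forced)
+ 2^10 (both interactions, 3 parents forced) - 1 (empty model).

Effects are addressed by bit masks over the ordered effect list (mains
first, then interactions), which keeps the enumeration order deterministic
and the model space cheap to store.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "CandidateEffectSet",
    "ModelSpec",
    "default_candidate_set",
    "is_hierarchical",
    "enumerate_models",
    "build_design",
    "build_full_design",
    "DegenerateDesignError",
]

#: refuse exhaustive enumeration beyond this many effects
MAX_EFFECTS = 24

DEFAULT_MAINS = (
    "mother_age",
    "education",
    "income",
    "garden",
    "n_children",
    "age_youngest",
    "marital_conflict",
    "psychopathology",
    "health_concerns",
    "work_changes",
    "work_stress",
    "father_involvement",
    "grandparent_care",
)

DEFAULT_INTERACTIONS = (
    ("grandparent_care", "age_youngest"),
    ("father_involvement", "age_youngest"),
)


class DegenerateDesignError(ValueError):
    """Raised when an included design column has zero variance."""


@dataclass(frozen=True)
class CandidateEffectSet:
    """Ordered universe of candidate effects: mains, then interactions."""

    mains: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.mains)) != len(self.mains):
            raise ValueError("main-effect names must be unique")
        for a, b in self.interactions:
            if a == b:
                raise ValueError(f"interaction {a}:{b} has identical parents")
            for parent in (a, b):
                if parent not in self.mains:
                    raise ValueError(
                        f"interaction parent '{parent}' is not a main effect")
        if len(set(self.interactions)) != len(self.interactions):
            raise ValueError("interactions must be unique")

    @property
    def n_effects(self) -> int:
        return len(self.mains) + len(self.interactions)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.mains + tuple(f"{a}:{b}" for a, b in self.interactions)

    def main_index(self, name: str) -> int:
        return self.mains.index(name)


def default_candidate_set() -> CandidateEffectSet:
    """The 15-effect default universe (13 mains, 2 shared-parent interactions)."""
    return CandidateEffectSet(DEFAULT_MAINS, DEFAULT_INTERACTIONS)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate regression model: an inclusion mask over the effects."""

    mask: int
    effects: CandidateEffectSet = field(repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.mask < (1 << self.effects.n_effects):
            raise ValueError(f"mask {self.mask} out of range for "
                             f"{self.effects.n_effects} effects")
        if not is_hierarchical(self.mask, self.effects):
            raise ValueError(f"mask {self.mask} violates the hierarchy "
                             "(marginality) constraint")

    @property
    def included(self) -> tuple[int, ...]:
        """Indices of included effects, ascending."""
        return tuple(i for i in range(self.effects.n_effects)
                     if self.mask >> i & 1)

    @property
    def labels(self) -> tuple[str, ...]:
        all_labels = self.effects.labels
        return tuple(all_labels[i] for i in self.included)

    @property
    def n_params(self) -> int:
        """Included effects plus the intercept."""
        return len(self.included) + 1

    @property
    def variables(self) -> tuple[str, ...]:
        """Underlying dataset variables the model touches (mains only)."""
        names: list[str] = []
        n_mains = len(self.effects.mains)
        for i in self.included:
            if i < n_mains:
                names.append(self.effects.mains[i])
            else:
                a, b = self.effects.interactions[i - n_mains]
                names.extend((a, b))
        return tuple(dict.fromkeys(names))


def is_hierarchical(mask: int, effects: CandidateEffectSet) -> bool:
    """True iff every included interaction has both parent mains included."""
    n_mains = len(effects.mains)
    for j, (a, b) in enumerate(effects.interactions):
        if mask >> (n_mains + j) & 1:
            ia, ib = effects.main_index(a), effects.main_index(b)
            if not (mask >> ia & 1 and mask >> ib & 1):
                return False
    return True


def enumerate_models(effects: CandidateEffectSet) -> list[ModelSpec]:
    """All hierarchically valid non-empty models, ascending by mask.

    Refuses candidate sets with more than 24 effects (2^24 subsets is the
    practical exhaustive-enumeration limit).
    """
    e = effects.n_effects
    if e > MAX_EFFECTS:
        raise ValueError(f"{e} effects exceed the enumeration limit "
                         f"of {MAX_EFFECTS}")
    n_mains = len(effects.mains)
    # precompute (interaction bit, required parent bits) pairs
    reqs = []
    for j, (a, b) in enumerate(effects.interactions):
        parents = (1 << effects.main_index(a)) | (1 << effects.main_index(b))
        reqs.append((1 << (n_mains + j), parents))
    out = []
    for mask in range(1, 1 << e):
        if all(not mask & ibit or (mask & par) == par for ibit, par in reqs):
            out.append(ModelSpec(mask, effects))
    return out


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=1)
    return (col - col.mean()) / sd


def build_full_design(dataset: pd.DataFrame, effects: CandidateEffectSet,
                      outcome: str = "harsh_discipline"
                      ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix over the *whole* candidate set, for the CV engine.

    Rows are listwise-complete over the union of all candidate variables and
    the outcome, so every candidate model is fit and scored on identical
    rows.  Columns: intercept, then the mains as given, then one product
    column per interaction formed from the standardized parents.

    Returns ``(X, y, column_names)``; effect ``i`` of a mask lives in column
    ``i + 1``.
    """
    needed = list(effects.mains) + [outcome]
    missing = [v for v in needed if v not in dataset.columns]
    if missing:
        raise KeyError(f"dataset lacks required columns: {missing}")
    sub = dataset[needed].dropna()
    n = len(sub)
    d = 1 + effects.n_effects
    X = np.empty((n, d))
    X[:, 0] = 1.0
    names = ["intercept"]
    for i, m in enumerate(effects.mains):
        col = sub[m].to_numpy(dtype=float)
        if col.std(ddof=1) == 0:
            raise DegenerateDesignError(f"column '{m}' has zero variance")
        X[:, 1 + i] = col
        names.append(m)
    n_mains = len(effects.mains)
    for j, (a, b) in enumerate(effects.interactions):
        prod = (_standardize(sub[a].to_numpy(dtype=float))
                * _standardize(sub[b].to_numpy(dtype=float)))
        if prod.std(ddof=1) == 0:
            raise DegenerateDesignError(
                f"interaction column '{a}:{b}' has zero variance")
        X[:, 1 + n_mains + j] = prod
        names.append(f"{a}:{b}")
    y = sub[outcome].to_numpy(dtype=float)
    return X, y, names


def build_design(dataset: pd.DataFrame, spec: ModelSpec,
                 outcome: str = "harsh_discipline"
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Model matrix and response for a single model.

    Listwise-complete over the model's own variables only.  Interaction
    columns are products of the standardized parent columns.
    """
    needed = list(spec.variables) + [outcome]
    sub = dataset[needed].dropna()
    cols = {"intercept": np.ones(len(sub))}
    n_mains = len(spec.effects.mains)
    for i in spec.included:
        if i < n_mains:
            name = spec.effects.mains[i]
            col = sub[name].to_numpy(dtype=float)
        else:
            a, b = spec.effects.interactions[i - n_mains]
            name = f"{a}:{b}"
            col = (_standardize(sub[a].to_numpy(dtype=float))
                   * _standardize(sub[b].to_numpy(dtype=float)))
        if col.std(ddof=1) == 0:
            raise DegenerateDesignError(f"column '{name}' has zero variance")
        cols[name] = col
    X = pd.DataFrame(cols, index=sub.index)
    return X, sub[outcome]
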