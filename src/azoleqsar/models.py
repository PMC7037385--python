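"""Multilinear QSAR models: the four published azole/aromatase equations as
packaged predictors, ordinary least-squares fitting, and genetic-algorithm
descriptor-subset selection with leave-one-out Q² as fitness.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CollinearityError, MissingDescriptorError, UnitsError
from .validation import q2_loo

#: minimum compounds-per-descriptor ratio before a fit warns
RATIO_RULE = 5.0


class RatioRuleWarning(UserWarning):
    """Fewer than 5 training compounds per descriptor."""


@dataclass
class DescriptorVector:
    """Named descriptor values for one compound, with optional method/units
    tags for electronic entries (``units[name] = (method, units)``)."""

    values: dict[str, float]
    units: dict[str, tuple[str, str]] = field(default_factory=dict)
    compound_id: str = ""


@dataclass
class ModelSpec:
    """A multilinear regression model: intercept plus (descriptor, coefficient)
    terms, expected unit tags for electronic descriptors, and fit statistics."""

    name: str
    activity: str  # "pIC50" or "pEC50"
    azole_class: str
    intercept: float
    terms: list[tuple[str, float]]
    expected_units: dict[str, tuple[str, str]] = field(default_factory=dict)
    stats: dict[str, float] = field(default_factory=dict)

    @property
    def descriptor_names(self) -> list[str]:
        return [n for n, _ in self.terms]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelSpec":
        if isinstance(source, Path) or (isinstance(source, str) and "{" not in source):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        d["terms"] = [tuple(t) for t in d["terms"]]
        d["expected_units"] = {k: tuple(v) for k, v in d.get("expected_units", {}).items()}
        return cls(**d)


def builtin_models() -> list[ModelSpec]:
    """The four published azole/aromatase MLR models, coefficients as printed.

    Electronic-descriptor unit tags record the working assumption (ω_HF in
    hartree-consistent units, PM7 LUMO in eV, PM7 HOMO−1 on the hartree scale);
    prediction refuses descriptor vectors whose tags disagree.
    """
    return [
        ModelSpec(
            name="triazole_antagonist",
            activity="pIC50",
            azole_class="triazole",
            intercept=1.4676,
            terms=[
                ("omega_HF", 488.5007),
                ("E_LUMO_PM7", 4.3535),
                ("Eta_shape_Y", 5.6602),
            ],
            expected_units={
                "omega_HF": ("HF", "hartree"),
                "E_LUMO_PM7": ("PM7", "eV"),
            },
            stats={"R2": 0.87, "Q2_LOO": 0.79, "Q2_LMO": 0.74, "dK": 0.06,
                   "n_train": 15},
        ),
        ModelSpec(
            name="diazole_antagonist",
            activity="pIC50",
            azole_class="diazole",
            intercept=3.5936,
            terms=[
                ("E_HOMONL_PM7", -22.4173),
                ("ETA_etaP_B", -103.9622),
                ("NRS", -0.6724),
            ],
            expected_units={"E_HOMONL_PM7": ("PM7", "hartree")},
            stats={"R2": 0.75, "Q2_LOO": 0.62, "Q2_LMO": 0.58, "dK": 0.11,
                   "n_train": 26},
        ),
        ModelSpec(
            name="diazole_agonist",
            activity="pEC50",
            azole_class="diazole",
            intercept=8.6983,
            terms=[
                ("Qmax_pos_PM7", -0.7252),
                ("Eta_dAlpha_B", -19.4372),
                ("Eta_betans_d", 1.1130),
            ],
            expected_units={"Qmax_pos_PM7": ("PM7", "e")},
            stats={"R2": 0.85, "Q2_LOO": 0.80, "Q2_LMO": 0.78, "dK": 0.21,
                   "n_train": 17},
        ),
        ModelSpec(
            name="thiazole_agonist",
            activity="pEC50",
            azole_class="monoazole",
            intercept=7.3704,
            terms=[
                ("GGI9", -8.0767),
                ("F03_C_C", 0.1177),
                ("F04_N_O", 0.5873),
            ],
            stats={"R2": 0.87, "Q2_LOO": 0.79, "Q2_LMO": 0.74, "n_train": 18},
        ),
    ]


def predict(model: ModelSpec, d: DescriptorVector | dict) -> float:
    """Evaluate ``intercept + Σ coefficient · descriptor`` for one compound.

    Raises :class:`MissingDescriptorError` naming any absent descriptor and
    :class:`UnitsError` when a tagged descriptor disagrees with the model's
    expected method/units.
    """
    if isinstance(d, dict):
        d = DescriptorVector(values=d)
    missing = [n for n in model.descriptor_names if n not in d.values]
    if missing:
        raise MissingDescriptorError(
            f"{model.name}: missing descriptor(s) {missing} for "
            f"{d.compound_id or 'compound'}"
        )
    for name, expected in model.expected_units.items():
        got = d.units.get(name)
        if got is not None and tuple(got) != tuple(expected):
            raise UnitsError(
                f"{model.name}: descriptor {name!r} tagged {got}, expected {expected}"
            )
    return model.intercept + sum(c * d.values[n] for n, c in model.terms)


def predict_table(model: ModelSpec, table: pd.DataFrame) -> pd.Series:
    """Vectorised prediction over a wide descriptor DataFrame."""
    missing = [n for n in model.descriptor_names if n not in table.columns]
    if missing:
        raise MissingDescriptorError(f"{model.name}: missing column(s) {missing}")
    out = pd.Series(model.intercept, index=table.index, dtype=float)
    for name, coef in model.terms:
        out = out + coef * table[name].astype(float)
    out.name = model.activity
    return out


@dataclass
class OLSFit:
    """Result of an ordinary least-squares fit."""

    model: ModelSpec
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float


def _as_matrix(X, names=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    return X, list(names)


def fit_ols(X, y, names=None, activity: str = "pIC50",
            model_name: str = "ols") -> OLSFit:
    """Least-squares fit of ``y = b0 + X b`` with collinearity diagnostics.

    Raises :class:`CollinearityError` naming the offending columns when the
    design matrix is rank deficient, and warns when the compounds-per-descriptor
    ratio drops below 5.
    """
    Xm, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    if n / p < RATIO_RULE:
        warnings.warn(
            f"{n} compounds for {p} descriptors (ratio {n / p:.1f} < {RATIO_RULE:g})",
            RatioRuleWarning,
            stacklevel=2,
        )
    design = np.column_stack([np.ones(n), Xm])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # name the columns loading on the null space
        _, s, vt = np.linalg.svd(design)
        null = np.abs(vt[-1][1:])  # drop intercept component
        bad = [names[i] for i in np.nonzero(null > 0.1 * null.max())[0]]
        raise CollinearityError(f"rank-deficient design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    tss = float(np.sum((y - y.mean()) ** 2))
    tiny = n * (1e-12 * max(1.0, float(np.abs(y).max()))) ** 2
    r2 = 1.0 - float(resid @ resid) / tss if tss > tiny else 0.0
    spec = ModelSpec(
        name=model_name,
        activity=activity,
        azole_class="",
        intercept=float(coef[0]),
        terms=[(nm, float(c)) for nm, c in zip(names, coef[1:])],
        stats={"R2": r2, "n_train": n},
    )
    return OLSFit(model=spec, fitted=fitted, residuals=resid, r2=r2)


@dataclass
class GAConfig:
    """Genetic-algorithm settings; defaults give a 10,000-evaluation budget
    (population × generations) with the published crossover/mutation rates."""

    population: int = 100
    generations: int = 100
    crossover: float = 0.8
    mutation: float = 0.2
    seed: int = 0
    elitism: int = 1


@dataclass
class GAResult:
    subset: tuple[str, ...]
    fit: OLSFit
    q2_loo: float
    evaluations: int
    history: list[float]


def _loo_fitness(Xm, y, cols, cache):
    key = cols
    if key in cache:
        return cache[key]
    try:
        val = q2_loo(Xm[:, list(cols)], y)
    except Exception:
        val = -np.inf
    cache[key] = val
    return val


def ga_select(X, y, k: int, config: GAConfig | None = None, names=None,
              mode: str = "fixed") -> GAResult:
    """Select the descriptor subset maximising leave-one-out Q² by a genetic
    algorithm (binary-mask chromosomes, uniform crossover, bit-swap mutation,
    elitism of 1; deterministic for a given seed).

    ``mode="fixed"`` searches subsets of exactly ``k`` descriptors,
    ``mode="upto"`` sizes 1..k.  Requires n/k ≥ 5 (ratio rule).
    """
    config = config or GAConfig()
    Xm, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if not 1 <= k <= p:
        raise ValueError(f"infeasible subset size k={k} for p={p}")
    if n / k < RATIO_RULE:
        raise ValueError(
            f"n/k = {n}/{k} violates the {RATIO_RULE:g}:1 compounds-per-descriptor rule"
        )
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, float] = {}

    def random_subset():
        size = k if mode == "fixed" else int(rng.integers(1, k + 1))
        return tuple(sorted(rng.choice(p, size=size, replace=False).tolist()))

    def repair(bits: set) -> tuple:
        bits = set(bits)
        limit = k
        if mode == "fixed":
            while len(bits) > k:
                bits.remove(int(rng.choice(sorted(bits))))
            while len(bits) < k:
                bits.add(int(rng.choice([i for i in range(p) if i not in bits])))
        else:
            while len(bits) > limit:
                bits.remove(int(rng.choice(sorted(bits))))
            if not bits:
                bits.add(int(rng.integers(p)))
        return tuple(sorted(bits))

    pop = [random_subset() for _ in range(config.population)]
    fitness = [_loo_fitness(Xm, y, c, cache) for c in pop]
    history = [max(fitness)]
    for _gen in range(config.generations - 1):
        order = np.argsort(fitness)[::-1]
        new_pop = [pop[order[i]] for i in range(config.elitism)]
        while len(new_pop) < config.population:
            # tournament selection, size 2
            a, b = rng.integers(len(pop), size=2)
            p1 = pop[a] if fitness[a] >= fitness[b] else pop[b]
            a, b = rng.integers(len(pop), size=2)
            p2 = pop[a] if fitness[a] >= fitness[b] else pop[b]
            if rng.random() < config.crossover:
                union = sorted(set(p1) | set(p2))
                mask = rng.random(len(union)) < 0.5
                child = {g for g, m in zip(union, mask) if m}
                child |= set(p1) & set(p2)  # shared genes always inherited
            else:
                child = set(p1)
            if rng.random() < config.mutation and child:
                out_gene = int(rng.choice(sorted(child)))
                candidates = [i for i in range(p) if i not in child]
                child.discard(out_gene)
                if candidates:
                    child.add(int(rng.choice(candidates)))
            new_pop.append(repair(child))
        pop = new_pop
        fitness = [_loo_fitness(Xm, y, c, cache) for c in pop]
        history.append(max(fitness))
    best_idx = int(np.argmax(fitness))
    best = pop[best_idx]
    sub_names = [names[i] for i in best]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RatioRuleWarning)
        fit = fit_ols(Xm[:, list(best)], y, names=sub_names, model_name="ga_mlr")
    return GAResult(
        subset=tuple(sub_names),
        fit=fit,
        q2_loo=fitness[best_idx],
        evaluations=len(cache),
        history=history,
    )
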