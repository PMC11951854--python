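"""Simulated relationship patterns and canonical fixtures.

This module generates every data pattern used to characterize the
coefficient: Anscombe's quartet (hard-coded canonical 1973 values), generic
numerical relationships (independent noise, non-coexistence, quadratic,
two-lines mixtures), categorical mixes, and two-cluster substructure
arrangements.  It also exposes reference Pearson/Spearman coefficients for
side-by-side comparison.

All generators are deterministic given their seed; defaults for the
parameters not fixed by the constructions themselves (noise scales, slopes,
category mixing weights, blob separation) are documented per generator and
in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .partitioning import CATEGORICAL, NUMERICAL, DataVector, as_data_vector

# Canonical Anscombe (1973) quartet; datasets I-III share the x vector.
_ANSCOMBE_X = (10.0, 8.0, 13.0, 9.0, 11.0, 14.0, 6.0, 4.0, 12.0, 7.0, 5.0)
_ANSCOMBE_Y = {
    "I": (8.04, 6.95, 7.58, 8.81, 8.33, 9.96, 7.24, 4.26, 10.84, 4.82, 5.68),
    "II": (9.14, 8.14, 8.74, 8.77, 9.26, 8.10, 6.13, 3.10, 9.13, 7.26, 4.74),
    "III": (7.46, 6.77, 12.74, 7.11, 7.81, 8.84, 6.08, 5.39, 8.15, 6.42, 5.73),
}
_ANSCOMBE_IV_X = (8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 19.0, 8.0, 8.0, 8.0)
_ANSCOMBE_IV_Y = (6.58, 5.76, 7.71, 8.84, 8.47, 7.04, 5.25, 12.50, 5.56, 7.91, 6.89)

NUMERICAL_PATTERNS = ("random", "non_coexistence", "quadratic", "two_lines")
CATEGORICAL_PATTERNS = ("two_cat_indep", "two_cat_assoc", "cat_num_indep", "cat_num_assoc")
SUBSTRUCTURE_ORIENTATIONS = ("diagonal", "horizontal", "vertical")


@dataclass(frozen=True, eq=False)
class PatternDataset:
    """A simulated variable pair plus the parameters that produced it."""

    x: DataVector
    y: DataVector
    pattern_name: str
    params: dict

    @property
    def n(self) -> int:
        return self.x.n

    def to_frame(self) -> pd.DataFrame:
        """Variables-as-rows frame (loadable by the matrix reader)."""
        names = self.params.get("variable_names", ("x", "y"))
        data = pd.DataFrame(
            [list(self.x.values), list(self.y.values)],
            index=list(names),
            columns=[f"s{i}" for i in range(self.n)],
        )
        data.index.name = "id"
        return data

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def anscombe() -> Dict[str, PatternDataset]:
    """The four canonical Anscombe (1973) datasets, keyed "I".."IV".

    Eleven points each; near-identical means, variances and Pearson
    correlation (~0.82) across the four, with radically different shapes.
    """
    out = {}
    for key in ("I", "II", "III"):
        out[key] = PatternDataset(
            x=as_data_vector(np.array(_ANSCOMBE_X)),
            y=as_data_vector(np.array(_ANSCOMBE_Y[key])),
            pattern_name=f"anscombe_{key}",
            params={"n": 11},
        )
    out["IV"] = PatternDataset(
        x=as_data_vector(np.array(_ANSCOMBE_IV_X)),
        y=as_data_vector(np.array(_ANSCOMBE_IV_Y)),
        pattern_name="anscombe_IV",
        params={"n": 11},
    )
    return out


def make_pattern(
    name: str,
    n: int = 100,
    seed: Optional[int] = 0,
    noise: Optional[float] = None,
) -> PatternDataset:
    """Simulate a numerical relationship pattern.

    random
        Two independent standard normals.
    non_coexistence
        Mutually exclusive activity: in half the objects x is high
        (U(5, 10)) while y idles near zero (|N(0, 0.3^2)|), and vice versa;
        halves are exactly balanced.
    quadratic
        x ~ U(-2, 2), y = x^2 + N(0, noise^2) with default noise 0.5.  The
        even symmetry defeats a two-cluster split but not a four-cluster one.
    two_lines
        Two exactly balanced linear components through the origin with
        slopes +3 and -3, x ~ U(0, 5), additive N(0, noise^2) with default
        noise 1.0.  Balancing the components pins Pearson/Spearman near 0.
    """
    if name not in NUMERICAL_PATTERNS:
        raise ValueError(f"unknown pattern {name!r}; choose from {NUMERICAL_PATTERNS}")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    rng = np.random.default_rng(seed)
    params = {"n": n, "seed": seed}
    if name == "random":
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
    elif name == "non_coexistence":
        noise = 0.3 if noise is None else noise
        half = n // 2
        group = rng.permutation(np.repeat([0, 1], [half, n - half]))
        high = rng.uniform(5.0, 10.0, size=n)
        low = np.abs(rng.normal(0.0, noise, size=n))
        x = np.where(group == 0, high, low)
        y = np.where(group == 0, low, high)
        params["noise"] = noise
    elif name == "quadratic":
        noise = 0.5 if noise is None else noise
        x = rng.uniform(-2.0, 2.0, size=n)
        y = x**2 + rng.normal(0.0, noise, size=n)
        params["noise"] = noise
    else:  # two_lines
        noise = 1.0 if noise is None else noise
        half = n // 2
        slope = np.where(rng.permutation(np.repeat([0, 1], [half, n - half])) == 0, 3.0, -3.0)
        x = rng.uniform(0.0, 5.0, size=n)
        y = slope * x + rng.normal(0.0, noise, size=n)
        params.update(noise=noise, slopes=(3.0, -3.0))
    return PatternDataset(
        x=as_data_vector(x), y=as_data_vector(y), pattern_name=name, params=params
    )


def make_categorical_pattern(
    name: str,
    n: int = 100,
    seed: Optional[int] = 0,
) -> PatternDataset:
    """Simulate patterns involving categorical variables.

    cat_num_assoc
        z drawn uniformly over {A, B, C}; y per category from N(0, 0.5^2),
        N(1, 0.25^2) and N(1, 0.75^2) respectively, so low-y objects are
        mostly category A.
    cat_num_indep
        z uniform over {A, B, C}; y ~ N(0, 1) independently.
    two_cat_assoc
        z uniform over {A, B, C}; binary w with blue over-represented given
        z=A (P = 0.85), orange over-represented (less strongly) given z=B
        (P(blue) = 0.30), balanced given z=C.
    two_cat_indep
        w and z drawn independently and uniformly.

    For mixed patterns the categorical variable is returned as ``x`` and the
    numerical one as ``y``.
    """
    if name not in CATEGORICAL_PATTERNS:
        raise ValueError(f"unknown pattern {name!r}; choose from {CATEGORICAL_PATTERNS}")
    if n < 9:
        raise ValueError(f"n must be >= 9 so all three categories can appear, got {n}")
    rng = np.random.default_rng(seed)
    params = {"n": n, "seed": seed}
    z = rng.choice(np.array(["A", "B", "C"], dtype=object), size=n)
    if name == "cat_num_assoc":
        means = {"A": 0.0, "B": 1.0, "C": 1.0}
        sds = {"A": 0.5, "B": 0.25, "C": 0.75}
        y = np.array([rng.normal(means[c], sds[c]) for c in z])
        params.update(means=means, sds=sds, variable_names=("z", "y"))
        return PatternDataset(
            x=as_data_vector(z, kind=CATEGORICAL),
            y=as_data_vector(y),
            pattern_name=name,
            params=params,
        )
    if name == "cat_num_indep":
        y = rng.standard_normal(n)
        params["variable_names"] = ("z", "y")
        return PatternDataset(
            x=as_data_vector(z, kind=CATEGORICAL),
            y=as_data_vector(y),
            pattern_name=name,
            params=params,
        )
    if name == "two_cat_assoc":
        p_blue = {"A": 0.85, "B": 0.30, "C": 0.50}
        w = np.where(
            rng.random(n) < np.array([p_blue[c] for c in z]), "blue", "orange"
        ).astype(object)
        params.update(p_blue=p_blue, variable_names=("w", "z"))
    else:  # two_cat_indep
        w = rng.choice(np.array(["blue", "orange"], dtype=object), size=n)
        params["variable_names"] = ("w", "z")
    return PatternDataset(
        x=as_data_vector(w, kind=CATEGORICAL),
        y=as_data_vector(z, kind=CATEGORICAL),
        pattern_name=name,
        params=params,
    )


def make_substructure(
    orientation: str,
    n: int = 100,
    seed: Optional[int] = 0,
    separation: float = 8.0,
    spread: float = 1.0,
) -> PatternDataset:
    """Two equal-size Gaussian blobs at a given arrangement.

    Diagonal displacement makes the two-cluster splits of x and of y pick
    out the same objects (coefficient near 1); horizontal or vertical
    displacement leaves one variable uninformative (coefficient near 0).
    The default separation (8 standard deviations) keeps the blobs clearly
    distinct.
    """
    if orientation not in SUBSTRUCTURE_ORIENTATIONS:
        raise ValueError(
            f"unknown orientation {orientation!r}; choose from {SUBSTRUCTURE_ORIENTATIONS}"
        )
    if n < 4 or n % 2:
        raise ValueError(f"n must be even and >= 4, got {n}")
    rng = np.random.default_rng(seed)
    half = n // 2
    offsets = {
        "diagonal": (separation, separation),
        "horizontal": (separation, 0.0),
        "vertical": (0.0, separation),
    }[orientation]
    x = rng.normal(0.0, spread, size=n)
    y = rng.normal(0.0, spread, size=n)
    x[half:] += offsets[0]
    y[half:] += offsets[1]
    return PatternDataset(
        x=as_data_vector(x),
        y=as_data_vector(y),
        pattern_name=f"substructure_{orientation}",
        params={"n": n, "seed": seed, "separation": separation, "spread": spread},
    )


def reference_coefficients(x, y) -> Dict[str, float]:
    """Pearson and Spearman coefficients for a numerical pair."""
    xv = as_data_vector(x)
    yv = as_data_vector(y)
    if xv.kind != NUMERICAL or yv.kind != NUMERICAL:
        raise TypeError("reference coefficients are defined for numerical variables only")
    if xv.n < 3 or yv.n < 3:
        raise ValueError("need at least 3 observations")
    pearson = stats.pearsonr(xv.values, yv.values).statistic
    spearman = stats.spearmanr(xv.values, yv.values).statistic
    return {"pearson": float(pearson), "spearman": float(spearman)}
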