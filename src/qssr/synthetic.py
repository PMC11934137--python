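"""Synthetic descriptor tables and toy geometries with the structure the
analysis assumes.

The generator emulates the shape of a small ligand-parametrization campaign:
~22 ligands, a pool of correlated continuous descriptors (equicorrelated
standard multivariate normal -- one collinearity knob), a sparse linear
free-energy response carried by a few active descriptors plus Gaussian noise,
and a yield governed by a single-feature threshold mechanism (high side of
the cut yields 90%, low side 20%, with optional independent label flips).

Everything is reproducible from the spec's seed.  These are statistical
stand-ins: no quantum-chemistry physics is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .structures import Atom, Molecule
from .table import DescriptorTable

__all__ = ["SyntheticSpec", "generate_table", "generate_toy_complex"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic ligand campaign.

    ``noise_sd`` is in response units (kcal/mol); ``noise_relative`` (used
    when ``noise_sd`` is None) scales it to the analytic standard deviation
    of the noiseless response, default 0.15 -- a strong but not noiseless
    structure-selectivity signal.  ``yield_cut`` is on the (standardized)
    scale of the yield-governing descriptor.
    """

    n_ligands: int = 22
    n_descriptors: int = 10
    correlation: float = 0.3
    active_subset: tuple[int, ...] = (0, 2, 5, 8)
    coefficients: tuple[float, ...] = (1.0, -0.8, 0.6, -0.5)
    noise_sd: float | None = None
    noise_relative: float = 0.15
    yield_feature: int = 0
    yield_cut: float = 0.0
    yield_high: float = 90.0
    yield_low: float = 20.0
    yield_flip_rate: float = 0.0
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.n_descriptors
        if self.n_ligands < 2 or p < 1:
            raise ValueError("need n_ligands >= 2 and n_descriptors >= 1")
        if len(self.active_subset) != len(self.coefficients):
            raise ValueError("active_subset and coefficients lengths differ")
        if len(self.active_subset) > p or any(not 0 <= j < p for j in self.active_subset):
            raise ValueError("active_subset indices out of range")
        if len(set(self.active_subset)) != len(self.active_subset):
            raise ValueError("active_subset has duplicates")
        # equicorrelated covariance is positive definite iff -1/(p-1) < rho < 1
        lo = -1.0 / (p - 1) if p > 1 else -math.inf
        if not lo < self.correlation < 1.0:
            raise ValueError(
                f"correlation {self.correlation} gives a non-positive-definite "
                f"covariance for p={p} (need {lo:.3g} < rho < 1)"
            )
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.yield_flip_rate < 0.5:
            raise ValueError("yield_flip_rate must be in [0, 0.5)")

    @property
    def signal_sd(self) -> float:
        """Analytic sd of the noiseless response under the equicorrelated model."""
        beta = np.asarray(self.coefficients, dtype=float)
        rho = self.correlation
        var = (1 - rho) * float(beta @ beta) + rho * float(beta.sum()) ** 2
        return math.sqrt(var)

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return self.noise_relative * self.signal_sd

    @property
    def descriptor_names(self) -> list[str]:
        return [f"d{j + 1:02d}" for j in range(self.n_descriptors)]

    @property
    def active_names(self) -> tuple[str, ...]:
        names = self.descriptor_names
        return tuple(names[j] for j in self.active_subset)


def generate_table(spec: SyntheticSpec) -> DescriptorTable:
    """Draw a full synthetic campaign table from the spec.

    Descriptors: zero-mean unit-variance equicorrelated multivariate normal.
    Response: sum of coefficient * active descriptor + N(0, noise_sd).
    Yield: ``yield_high`` above the cut on the governing descriptor,
    ``yield_low`` below, each label flipped with ``yield_flip_rate``.
    Split: seeded random train/test tags (``test_fraction`` held out).
    """
    rng = np.random.default_rng(spec.seed)
    n, p, rho = spec.n_ligands, spec.n_descriptors, spec.correlation

    # X = sqrt(rho) * shared + sqrt(1-rho) * idiosyncratic gives exactly the
    # equicorrelated covariance without a Cholesky factorization
    if rho >= 0:
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, p))
        X = math.sqrt(rho) * shared + math.sqrt(1 - rho) * own
    else:
        cov = (1 - rho) * np.eye(p) + rho * np.ones((p, p))
        X = rng.multivariate_normal(np.zeros(p), cov, size=n)

    beta = np.asarray(spec.coefficients, dtype=float)
    response = X[:, list(spec.active_subset)] @ beta
    response = response + rng.normal(0.0, spec.effective_noise_sd, size=n)

    high_side = X[:, spec.yield_feature] > spec.yield_cut
    flips = rng.random(n) < spec.yield_flip_rate
    is_high = high_side ^ flips
    yields = np.where(is_high, spec.yield_high, spec.yield_low)

    tags = np.array(["train"] * n, dtype=object)
    n_test = max(1, round(n * spec.test_fraction))
    tags[rng.choice(n, size=n_test, replace=False)] = "test"

    df = pd.DataFrame(X, columns=spec.descriptor_names)
    df.insert(0, "ligand_id", [f"L{i + 1}" for i in range(n)])
    df["response"] = response
    df["yield_percent"] = yields
    df["split"] = tags
    provenance = {
        "_generator": {
            "kind": "synthetic-equicorrelated-gaussian",
            "spec": asdict(spec),
            "effective_noise_sd": spec.effective_noise_sd,
        }
    }
    return DescriptorTable(df=df, provenance=provenance)


def generate_toy_complex(
    n_atoms: int,
    shell_radius_range: tuple[float, float] = (1.5, 3.5),
    seed: int = 0,
    elements: tuple[str, ...] = ("H", "C", "N", "O", "F"),
) -> Molecule:
    """A toy metal complex: a central Co plus atoms uniform in a spherical shell.

    ``n_atoms`` counts the shell atoms (0 gives the bare metal); positions are
    uniform in shell volume.  Used as geometry fixtures for the buried-volume
    and sterimol integrators.
    """
    r_lo, r_hi = shell_radius_range
    if not 0 <= r_lo < r_hi:
        raise ValueError(f"invalid shell radius range {shell_radius_range}")
    if n_atoms < 0:
        raise ValueError("n_atoms must be >= 0")
    rng = np.random.default_rng(seed)
    atoms = [Atom("Co", 0.0, 0.0, 0.0)]
    for _ in range(n_atoms):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        u = rng.random()
        r = (u * (r_hi**3 - r_lo**3) + r_lo**3) ** (1.0 / 3.0)
        el = elements[rng.integers(len(elements))]
        atoms.append(Atom(el, *(r * v)))
    return Molecule(
        atoms=atoms,
        title=f"toy complex seed={seed} n={n_atoms}",
        annotations={"metal_center": 0},
    )
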