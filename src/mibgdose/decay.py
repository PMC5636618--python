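"""Iodine-131 decay scheme: beta spectra, discrete emissions and per-decay sampling.

The decay of :sup:`131`I to :sup:`131`Xe proceeds through several allowed
beta branches followed by gamma de-excitation; part of the gamma intensity is
converted to discrete conversion/Auger electrons.  This module compiles the
emission inventory into a :class:`DecayScheme`, evaluates the allowed-shape
beta spectrum of each branch (phase space times a nonrelativistic Fermi
Coulomb correction), and samples complete per-decay emission lists for the
Monte Carlo transport step.

The inventory ships as a plain-text data file (``data/i131_decay.csv``) whose
format permits other nuclides, although only :sup:`131`I data is bundled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import ALPHA_FS, MEC2_KEV

__all__ = [
    "BetaBranch",
    "DiscreteEmission",
    "DecayScheme",
    "load_i131_scheme",
    "beta_spectrum_density",
    "sample_decay",
]

_SPECTRUM_STEP_KEV = 1.0


@dataclass(frozen=True)
class BetaBranch:
    """One allowed beta-minus branch, characterised by its endpoint energy."""

    endpoint_kev: float
    intensity: float
    z_daughter: int = 54
    shape: str = "allowed"

    def __post_init__(self) -> None:
        if not self.endpoint_kev > 0:
            raise ValueError("endpoint energy must be positive")
        if not 0 < self.intensity <= 1:
            raise ValueError("branch intensity must be in (0, 1]")
        if self.shape != "allowed":
            raise ValueError("only allowed-shape branches are supported")


@dataclass(frozen=True)
class DiscreteEmission:
    """A monoenergetic photon or electron line with an expected yield per decay."""

    kind: str  # "photon" | "electron"
    energy_kev: float
    yield_per_decay: float

    def __post_init__(self) -> None:
        if self.kind not in ("photon", "electron"):
            raise ValueError(f"unknown emission kind {self.kind!r}")
        if not self.energy_kev > 0:
            raise ValueError("emission energy must be positive")
        if self.yield_per_decay < 0:
            raise ValueError("yield must be nonnegative")


@dataclass(frozen=True)
class DecayScheme:
    half_life_h: float
    beta_branches: tuple[BetaBranch, ...]
    discrete: tuple[DiscreteEmission, ...]
    nuclide: str = "I-131"

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValueError("half-life must be positive")
        total = sum(b.intensity for b in self.beta_branches)
        if total > 1.0 + 0.02:
            raise ValueError(f"beta intensities sum to {total:.4f} > 1")

    @property
    def decay_constant_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h

    @property
    def mean_beta_energy_kev(self) -> float:
        """Intensity-weighted mean energy of the sampled beta particle."""
        total_i = sum(b.intensity for b in self.beta_branches)
        return (
            sum(b.intensity * _branch_mean_energy(b) for b in self.beta_branches)
            / total_i
        )

    @property
    def mean_energy_per_decay_kev(self) -> float:
        """Mean total emitted energy per decay (betas + all discrete lines)."""
        beta = sum(b.intensity * _branch_mean_energy(b) for b in self.beta_branches)
        lines = sum(d.energy_kev * d.yield_per_decay for d in self.discrete)
        return beta + lines

    def mean_component_energy_kev(self) -> dict[str, float]:
        """Mean emitted energy per decay split by component."""
        out = {
            "beta": sum(b.intensity * _branch_mean_energy(b) for b in self.beta_branches),
            "electron": 0.0,
            "photon": 0.0,
        }
        for d in self.discrete:
            out[d.kind] += d.energy_kev * d.yield_per_decay
        return out


def load_i131_scheme(path: str | Path | None = None) -> DecayScheme:
    """Load the bundled :sup:`131`I decay scheme (or a user file in the same format).

    The file is a comment-headed CSV with columns ``kind,energy_kev,intensity``;
    the half-life (hours) and daughter atomic number are given in ``# key: value``
    header lines.
    """
    if path is None:
        text = resources.files("mibgdose.data").joinpath("i131_decay.csv").read_text()
    else:
        text = Path(path).read_text()

    half_life_h = None
    z_daughter = 54
    betas: list[BetaBranch] = []
    lines: list[DiscreteEmission] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if body.startswith("half_life_hours:"):
                half_life_h = float(body.split(":", 1)[1])
            elif body.startswith("z_daughter:"):
                z_daughter = int(body.split(":", 1)[1])
            continue
        if line.lower().startswith("kind,"):
            continue
        kind, energy, intensity = (tok.strip() for tok in line.split(","))
        if kind == "beta":
            betas.append(BetaBranch(float(energy), float(intensity), z_daughter))
        else:
            lines.append(DiscreteEmission(kind, float(energy), float(intensity)))
    if half_life_h is None:
        raise ValueError("decay file lacks a '# half_life_hours:' header")
    if not betas:
        raise ValueError("decay file contains no beta branch")
    return DecayScheme(half_life_h, tuple(betas), tuple(lines))


# ---------------------------------------------------------------------------
# allowed-shape beta spectrum
# ---------------------------------------------------------------------------

def _fermi_function(z_daughter: int, energy_kev: np.ndarray) -> np.ndarray:
    """Nonrelativistic Fermi Coulomb correction F(Z, E) for beta-minus decay.

    F = 2*pi*eta / (1 - exp(-2*pi*eta)) with eta = Z*alpha / beta, where
    beta = v/c of the emitted electron.  Adequate at the accuracy level the
    sphere dosimetry requires.
    """
    w = 1.0 + energy_kev / MEC2_KEV  # total energy, units of me c^2
    beta_v = np.sqrt(np.clip(1.0 - 1.0 / w**2, 1e-12, None))
    eta = ALPHA_FS * z_daughter / beta_v
    x = 2.0 * np.pi * eta
    return x / (-np.expm1(-x))


def _unnormalised_density(branch: BetaBranch, energy_kev: np.ndarray) -> np.ndarray:
    e = np.asarray(energy_kev, dtype=float)
    w = 1.0 + e / MEC2_KEV
    p = np.sqrt(np.clip(w**2 - 1.0, 0.0, None))
    q = np.clip(branch.endpoint_kev - e, 0.0, None)
    return _fermi_function(branch.z_daughter, e) * p * w * q**2


@lru_cache(maxsize=32)
def _branch_grid(branch: BetaBranch) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(energy grid, normalised pdf, cdf) for one branch on a ~1 keV grid."""
    n = max(int(branch.endpoint_kev / _SPECTRUM_STEP_KEV), 50)
    e = np.linspace(0.0, branch.endpoint_kev, n + 1)
    f = _unnormalised_density(branch, e)
    f[0] = 0.0  # zero momentum
    norm = np.trapezoid(f, e)
    pdf = f / norm
    cdf = np.concatenate(
        [[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(e))]
    )
    cdf /= cdf[-1]
    return e, pdf, cdf


def _branch_mean_energy(branch: BetaBranch) -> float:
    e, pdf, _ = _branch_grid(branch)
    return float(np.trapezoid(e * pdf, e))


def beta_spectrum_density(branch: BetaBranch, energy_kev) -> np.ndarray | float:
    """Normalised allowed-shape spectrum density (per keV) at ``energy_kev``.

    Raises ``ValueError`` outside the open interval (0, endpoint).
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e <= 0) or np.any(e >= branch.endpoint_kev):
        raise ValueError("energy must lie strictly inside (0, endpoint)")
    grid, pdf, _ = _branch_grid(branch)
    out = np.interp(e, grid, pdf)
    return float(out) if np.isscalar(energy_kev) else out


def sample_beta_energies(
    scheme: DecayScheme, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` beta energies from the branch-weighted spectrum (inverse CDF)."""
    intensities = np.array([b.intensity for b in scheme.beta_branches])
    probs = intensities / intensities.sum()
    which = rng.choice(len(probs), size=n, p=probs)
    u = rng.random(n)
    out = np.empty(n)
    for i, branch in enumerate(scheme.beta_branches):
        mask = which == i
        if not np.any(mask):
            continue
        grid, _, cdf = _branch_grid(branch)
        out[mask] = np.interp(u[mask], cdf, grid)
    return out


def sample_decay(
    scheme: DecayScheme, rng: np.random.Generator
) -> list[tuple[str, float]]:
    """Sample the emission list of a single decay.

    Returns one ``("beta", E)`` entry plus each discrete line included with
    Bernoulli probability equal to its yield.  Pure function of the generator
    state: identical states give identical lists.
    """
    emissions = [("beta", float(sample_beta_energies(scheme, 1, rng)[0]))]
    for line in scheme.discrete:
        if rng.random() < line.yield_per_decay:
            emissions.append((line.kind, line.energy_kev))
    return emissions
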