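"""Generate the synthetic sphere S-value reference table.

Deterministic chord-length model, algorithmically independent of the
event-by-event Monte Carlo in :mod:`mibgdose.transport`:

* electrons (beta continuum + discrete lines): expected deposit of a straight
  CSDA track computed by Gauss-Legendre quadrature over the uniform-source /
  isotropic-direction chord distribution of the sphere (no sampling);
* photons: energy-absorption-coefficient straight-path model,
  phi(E) = E_chord[1 - exp(-mu_en * d)], which is exact to first order in the
  optical thickness for the small spheres of interest.

Writes src/mibgdose/data/sphere_svalue_reference_synthetic.csv.  The table is
a synthetic stand-in constructed as an independent validation reference; it
is not a published data product.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from mibgdose.constants import KEV_TO_J
from mibgdose.decay import load_i131_scheme, _branch_grid
from mibgdose.transport import Sphere, _electron_deposit, _read_data_csv

MASSES_G = [0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0]


def chord_nodes(radius: float, n_u: int = 48, n_mu: int = 96):
    """Quadrature nodes/weights for the distance-to-boundary distribution."""
    xu, wu = np.polynomial.legendre.leggauss(n_u)
    u = 0.5 * (xu + 1.0)  # volume fraction in [0, 1]
    wu = 0.5 * wu
    xm, wm = np.polynomial.legendre.leggauss(n_mu)
    mu = xm  # direction cosine in [-1, 1]
    wm = 0.5 * wm
    rho = radius * u ** (1.0 / 3.0)
    RHO, MU = np.meshgrid(rho, mu, indexing="ij")
    W = np.outer(wu, wm)
    D = -RHO * MU + np.sqrt(RHO**2 * MU**2 + radius**2 - RHO**2)
    return D.ravel(), W.ravel()


def electron_phi(energies_kev: np.ndarray, d: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Mean absorbed fraction for electrons of each energy."""
    out = np.empty(len(energies_kev))
    for i, e in enumerate(energies_kev):
        dep = _electron_deposit(np.full(len(d), e), d, 1.0)
        out[i] = np.sum(w * dep) / e
    return out


def photon_phi(energies_kev: np.ndarray, d: np.ndarray, w: np.ndarray) -> np.ndarray:
    df = _read_data_csv("water_photon_mu_en.csv")
    mu_en = np.exp(
        np.interp(
            np.log(energies_kev),
            np.log(df["energy_kev"].to_numpy()),
            np.log(df["mu_en_cm2_g"].to_numpy()),
        )
    )
    return np.array([np.sum(w * (1.0 - np.exp(-m * d))) for m in mu_en])


def s_reference(mass_g: float) -> float:
    scheme = load_i131_scheme()
    sphere = Sphere(mass_g)
    d, w = chord_nodes(sphere.radius_cm)
    dep_per_decay = 0.0
    for branch in scheme.beta_branches:
        e, pdf, _ = _branch_grid(branch)
        e, pdf = e[1:], pdf[1:]  # drop the zero-energy node
        phi = electron_phi(e, d, w)
        dep_per_decay += branch.intensity * np.trapezoid(pdf * e * phi, e)
    e_lines = np.array([l.energy_kev for l in scheme.discrete if l.kind == "electron"])
    y_lines = np.array([l.yield_per_decay for l in scheme.discrete if l.kind == "electron"])
    dep_per_decay += float(np.sum(y_lines * e_lines * electron_phi(e_lines, d, w)))
    p_lines = np.array([l.energy_kev for l in scheme.discrete if l.kind == "photon"])
    py = np.array([l.yield_per_decay for l in scheme.discrete if l.kind == "photon"])
    dep_per_decay += float(np.sum(py * p_lines * photon_phi(p_lines, d, w)))
    return dep_per_decay * KEV_TO_J / (mass_g * 1e-3)


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "src/mibgdose/data/sphere_svalue_reference_synthetic.csv"
    lines = [
        "# Synthetic reference sphere S-values for I-131 in unit-density water,",
        "# computed by the deterministic chord-length quadrature model in",
        "# scripts/make_sphere_reference.py (independent of the event-by-event",
        "# Monte Carlo; see docs/methods.md). Not a published data product.",
        "mass_g,s_gy_per_bq_s,provenance",
    ]
    for m in MASSES_G:
        s = s_reference(m)
        lines.append(f"{m},{s:.6e},chord_quadrature_v1")
        print(f"mass {m:6.2f} g  S = {s:.6e} Gy/(Bq s)")
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
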