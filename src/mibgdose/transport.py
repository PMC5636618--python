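"""Event-by-event Monte Carlo transport in unit-density water spheres.

Self-dose sphere model: decays are sampled uniformly in the sphere volume with
isotropic emission; every emission of a decay is transported and the energy
deposited inside the sphere is scored per history, split into three source
components (beta continuum, discrete conversion/Auger electrons, photons with
all their secondaries).  The absorbed dose per unit cumulated activity — the
sphere S-value of the MIRD schema — follows as mean deposited energy per
decay divided by the sphere mass.

Physics model
-------------
Electrons: continuous slowing-down along a straight track using tabulated
collision stopping power; a track cut by the sphere surface escapes with its
residual energy (closed-form via the CSDA range table, no stepping).
Bremsstrahlung is neglected (radiative yield in water < 1% below ~1 MeV), as
is multiple-scattering path detour.

Photons: analog transport with free paths from the total interaction
coefficient (tabulated photoelectric + analytic Klein-Nishina incoherent);
photoelectric absorption transfers the full photon energy to a secondary
electron; Compton scattering samples the scattered-photon energy from the
Klein-Nishina distribution (Kahn-style composition/rejection), hands the
recoil electron to the electron model at its kinematic angle, and keeps
tracking the scattered photon.  Photons below 1 keV deposit locally.
Rayleigh scattering and fluorescence are neglected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import KEV_TO_J, MEC2_KEV, N_E_WATER_PER_G, R_E_CM2
from .decay import DecayScheme, sample_beta_energies

__all__ = [
    "Sphere",
    "TransportResult",
    "SValue",
    "transport_electron",
    "transport_photon",
    "simulate_sphere",
    "s_value",
    "sweep_svalues",
    "compare_to_reference",
    "load_reference_table",
]

E_CUT_PHOTON_KEV = 1.0
COMPONENTS = ("beta", "electron", "photon")


@dataclass(frozen=True)
class Sphere:
    """Homogeneous water sphere of given mass; radius derived from density."""

    mass_g: float
    density_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if not self.mass_g > 0 or not self.density_g_cm3 > 0:
            raise ValueError("mass and density must be positive")

    @property
    def radius_cm(self) -> float:
        volume = self.mass_g / self.density_g_cm3
        return (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class TransportResult:
    """Per-component energy bookkeeping of one simulation run."""

    n_histories: int
    sphere: Sphere
    seed: int | None
    energy_emitted_kev: dict[str, float]
    energy_deposited_kev: dict[str, float]
    energy_escaped_kev: float
    absorbed_fraction: dict[str, float]
    absorbed_fraction_total: float
    mc_standard_error: dict[str, float]
    mc_standard_error_total: float
    per_history: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for comp in COMPONENTS:
            if not 0.0 <= self.absorbed_fraction[comp] <= 1.0 + 1e-12:
                raise ValueError(f"absorbed fraction out of [0,1] for {comp}")

    @property
    def total_deposited_kev(self) -> float:
        return sum(self.energy_deposited_kev.values())

    @property
    def total_emitted_kev(self) -> float:
        return sum(self.energy_emitted_kev.values())


@dataclass(frozen=True)
class SValue:
    """Absorbed dose per unit cumulated activity, Gy/(Bq s), with MC uncertainty."""

    value: float
    uncertainty: float
    sphere: Sphere
    n_histories: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.value < 0 or self.uncertainty < 0:
            raise ValueError("S-value and uncertainty must be nonnegative")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "s_gy_per_bq_s": self.value,
            "uncertainty_gy_per_bq_s": self.uncertainty,
            "sphere_mass_g": self.sphere.mass_g,
            "density_g_cm3": self.sphere.density_g_cm3,
            "n_histories": self.n_histories,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SValue":
        d = json.loads(Path(path).read_text())
        return cls(
            d["s_gy_per_bq_s"],
            d["uncertainty_gy_per_bq_s"],
            Sphere(d["sphere_mass_g"], d.get("density_g_cm3", 1.0)),
            d.get("n_histories", 0),
            d.get("seed"),
        )


# ---------------------------------------------------------------------------
# interaction data
# ---------------------------------------------------------------------------

def _read_data_csv(name: str) -> pd.DataFrame:
    with resources.files("mibgdose.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


@lru_cache(maxsize=1)
def _electron_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fine log grid of (E keV, stopping keV cm2/g, CSDA range g/cm2 from 1 keV)."""
    df = _read_data_csv("water_electron_stopping.csv")
    e_tab = df["energy_kev"].to_numpy()
    s_tab = df["stopping_mev_cm2_g"].to_numpy() * 1000.0  # keV cm2/g
    e = np.geomspace(e_tab[0], e_tab[-1], 800)
    s = np.exp(np.interp(np.log(e), np.log(e_tab), np.log(s_tab)))
    from scipy.integrate import cumulative_trapezoid

    r = cumulative_trapezoid(1.0 / s, e, initial=0.0)
    return e, s, r


def csda_range_g_cm2(energy_kev) -> np.ndarray | float:
    """CSDA range (residual range down to 1 keV) in g/cm2."""
    e_grid, _, r_grid = _electron_tables()
    e = np.clip(np.asarray(energy_kev, dtype=float), e_grid[0], e_grid[-1])
    out = np.interp(e, e_grid, r_grid)
    return float(out) if np.isscalar(energy_kev) else out


def _residual_energy_kev(range_g_cm2: np.ndarray) -> np.ndarray:
    e_grid, _, r_grid = _electron_tables()
    rr = np.asarray(range_g_cm2, dtype=float)
    out = np.interp(rr, r_grid, e_grid)
    return np.where(rr <= 0.0, 0.0, out)


def _electron_deposit(energy_kev: np.ndarray, dist_cm: np.ndarray, density: float) -> np.ndarray:
    """Energy deposited inside the sphere by electrons with ``dist_cm`` to the surface."""
    e = np.asarray(energy_kev, dtype=float)
    e_grid, _, _ = _electron_tables()
    r_full = csda_range_g_cm2(e)
    r_res = r_full - np.asarray(dist_cm) * density
    e_out = _residual_energy_kev(np.clip(r_res, 0.0, None))
    dep = np.where(r_res <= 0.0, e, e - e_out)
    # sub-grid energies (< 1 keV) always deposit locally
    return np.where(e <= e_grid[0], e, dep)


@lru_cache(maxsize=1)
def _photoelectric_table() -> tuple[np.ndarray, np.ndarray]:
    df = _read_data_csv("water_photon_photoelectric.csv")
    return np.log(df["energy_kev"].to_numpy()), np.log(df["mu_pe_cm2_g"].to_numpy())


def mu_photoelectric_cm2_g(energy_kev) -> np.ndarray | float:
    """Photoelectric mass attenuation coefficient, log-log interpolated/extrapolated."""
    loge_tab, logmu_tab = _photoelectric_table()
    loge = np.log(np.asarray(energy_kev, dtype=float))
    # linear extrapolation in log-log beyond the table ends
    slope_lo = (logmu_tab[1] - logmu_tab[0]) / (loge_tab[1] - loge_tab[0])
    slope_hi = (logmu_tab[-1] - logmu_tab[-2]) / (loge_tab[-1] - loge_tab[-2])
    out = np.interp(loge, loge_tab, logmu_tab)
    out = np.where(loge < loge_tab[0], logmu_tab[0] + slope_lo * (loge - loge_tab[0]), out)
    out = np.where(loge > loge_tab[-1], logmu_tab[-1] + slope_hi * (loge - loge_tab[-1]), out)
    res = np.exp(out)
    return float(res) if np.isscalar(energy_kev) else res


def mu_incoherent_cm2_g(energy_kev) -> np.ndarray | float:
    """Incoherent (Compton) coefficient from the total Klein-Nishina cross-section."""
    k = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log1p(2.0 * k) / k)
    t2 = np.log1p(2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    sigma = 2.0 * np.pi * R_E_CM2 * (t1 + t2 - t3)
    res = sigma * N_E_WATER_PER_G
    return float(res) if np.isscalar(energy_kev) else res


# ---------------------------------------------------------------------------
# geometry and sampling helpers
# ---------------------------------------------------------------------------

def _dist_to_boundary(pos: np.ndarray, direction: np.ndarray, radius: float) -> np.ndarray:
    b = np.einsum("ij,ij->i", pos, direction)
    c = np.einsum("ij,ij->i", pos, pos) - radius**2
    disc = np.clip(b * b - c, 0.0, None)
    return -b + np.sqrt(disc)


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    mu = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - mu**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])


def _uniform_positions(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return _isotropic_directions(n, rng) * r[:, None]


def _rotate(u: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors ``u`` by polar angle arccos(cos_t), azimuth ``phi``."""
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    # orthonormal frame: pick helper axis least aligned with u
    helper = np.zeros_like(u)
    idx = np.argmin(np.abs(u), axis=1)
    helper[np.arange(len(u)), idx] = 1.0
    v1 = np.cross(u, helper)
    v1 /= np.linalg.norm(v1, axis=1, keepdims=True)
    v2 = np.cross(u, v1)
    out = (
        cos_t[:, None] * u
        + sin_t[:, None] * (np.cos(phi)[:, None] * v1 + np.sin(phi)[:, None] * v2)
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _sample_compton(energy_kev: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample scattered-photon energies from the Klein-Nishina distribution.

    Composition/rejection in the energy ratio eps = E'/E (standard analog
    Compton sampler); returns eps.
    """
    k = energy_kev / MEC2_KEV
    eps0 = 1.0 / (1.0 + 2.0 * k)
    alpha1 = -np.log(eps0)
    alpha2 = 0.5 * (1.0 - eps0**2)
    eps = np.empty_like(k)
    todo = np.arange(len(k))
    while todo.size:
        kk = k[todo]
        e0 = eps0[todo]
        a1 = alpha1[todo]
        a2 = alpha2[todo]
        r1, r2, r3 = rng.random(todo.size), rng.random(todo.size), rng.random(todo.size)
        cand = np.where(
            r1 < a1 / (a1 + a2),
            np.exp(-a1 * r2),
            np.sqrt(e0**2 + (1.0 - e0**2) * r2),
        )
        t = (1.0 - cand) / (kk * cand)
        sin2 = t * (2.0 - t)
        reject = 1.0 - cand * sin2 / (1.0 + cand**2)
        ok = r3 <= reject
        eps[todo[ok]] = cand[ok]
        todo = todo[~ok]
    return eps


# ---------------------------------------------------------------------------
# public scalar transport operations
# ---------------------------------------------------------------------------

def _check_inside(origin: np.ndarray, sphere: Sphere) -> np.ndarray:
    origin = np.atleast_2d(np.asarray(origin, dtype=float))
    if np.any(np.linalg.norm(origin, axis=1) > sphere.radius_cm * (1 + 1e-12)):
        raise ValueError("origin lies outside the sphere")
    return origin


def transport_electron(
    energy_kev: float, origin, direction, sphere: Sphere
) -> float:
    """Deposit of a single electron track (CSDA straight line); rest escapes."""
    if not energy_kev > 0:
        raise ValueError("energy must be positive")
    origin = _check_inside(origin, sphere)
    direction = np.atleast_2d(np.asarray(direction, dtype=float))
    direction = direction / np.linalg.norm(direction, axis=1, keepdims=True)
    d = _dist_to_boundary(origin, direction, sphere.radius_cm)
    dep = _electron_deposit(np.array([energy_kev]), d, sphere.density_g_cm3)
    return float(dep[0])


def transport_photon(
    energy_kev: float, origin, direction, sphere: Sphere, rng: np.random.Generator
) -> float:
    """Analog transport of one photon; returns total deposited energy (keV)."""
    if not energy_kev > 0:
        raise ValueError("energy must be positive")
    origin = _check_inside(origin, sphere)
    direction = np.atleast_2d(np.asarray(direction, dtype=float))
    direction = direction / np.linalg.norm(direction, axis=1, keepdims=True)
    dep = np.zeros(1)
    esc = np.zeros(1)
    _transport_photon_batch(
        origin.copy(),
        direction.copy(),
        np.array([float(energy_kev)]),
        np.zeros(1, dtype=np.intp),
        sphere,
        rng,
        dep,
        esc,
    )
    return float(dep[0])


# ---------------------------------------------------------------------------
# batch transport
# ---------------------------------------------------------------------------

def _transport_photon_batch(
    pos: np.ndarray,
    u: np.ndarray,
    e: np.ndarray,
    hid: np.ndarray,
    sphere: Sphere,
    rng: np.random.Generator,
    dep_hist: np.ndarray,
    esc_hist: np.ndarray,
    max_iter: int = 10_000,
) -> None:
    """Track a batch of photons to completion, scoring per-history deposits."""
    rho = sphere.density_g_cm3
    radius = sphere.radius_cm
    for _ in range(max_iter):
        if e.size == 0:
            return
        mu_pe = np.asarray(mu_photoelectric_cm2_g(e))
        mu_kn = np.asarray(mu_incoherent_cm2_g(e))
        mu_tot = (mu_pe + mu_kn) * rho  # 1/cm
        path = rng.exponential(1.0, e.size) / mu_tot
        d = _dist_to_boundary(pos, u, radius)
        escapes = path >= d
        np.add.at(esc_hist, hid[escapes], e[escapes])
        keep = ~escapes
        pos, u, e, hid = pos[keep], u[keep], e[keep], hid[keep]
        if e.size == 0:
            return
        pos = pos + path[keep][:, None] * u

        is_pe = rng.random(e.size) < (mu_pe[keep] / (mu_pe[keep] + mu_kn[keep]))
        # photoelectric: full transfer to a secondary electron (isotropic)
        if np.any(is_pe):
            n_pe = int(is_pe.sum())
            e_dir = _isotropic_directions(n_pe, rng)
            d_e = _dist_to_boundary(pos[is_pe], e_dir, radius)
            dep_e = _electron_deposit(e[is_pe], d_e, rho)
            np.add.at(dep_hist, hid[is_pe], dep_e)
            np.add.at(esc_hist, hid[is_pe], e[is_pe] - dep_e)
        # Compton scattering
        cm = ~is_pe
        if np.any(cm):
            e_in = e[cm]
            eps = _sample_compton(e_in, rng)
            e_sc = eps * e_in
            e_rec = e_in - e_sc
            k = e_in / MEC2_KEV
            cos_t = 1.0 - (1.0 - eps) / (k * eps)
            cos_t = np.clip(cos_t, -1.0, 1.0)
            phi = rng.uniform(0.0, 2.0 * np.pi, e_in.size)
            # recoil electron: kinematic polar angle, opposite azimuth
            tan_half = np.sqrt(np.clip((1.0 - cos_t) / (1.0 + cos_t), 0.0, None))
            with np.errstate(divide="ignore"):
                cot_e = (1.0 + k) * tan_half
            cos_e = cot_e / np.sqrt(1.0 + cot_e**2)
            rec_dir = _rotate(u[cm], cos_e, phi + np.pi)
            d_rec = _dist_to_boundary(pos[cm], rec_dir, radius)
            dep_rec = _electron_deposit(e_rec, d_rec, rho)
            np.add.at(dep_hist, hid[cm], dep_rec)
            np.add.at(esc_hist, hid[cm], e_rec - dep_rec)
            # scattered photon continues
            u_cm = _rotate(u[cm], cos_t, phi)
            low = e_sc < E_CUT_PHOTON_KEV
            if np.any(low):
                np.add.at(dep_hist, hid[cm][low], e_sc[low])
            keep_sc = ~low
            pos = pos[cm][keep_sc]
            u = u_cm[keep_sc]
            e = e_sc[keep_sc]
            hid = hid[cm][keep_sc]
        else:
            pos = pos[:0]
            u = u[:0]
            e = e[:0]
            hid = hid[:0]
    raise RuntimeError("photon transport did not terminate")


def simulate_sphere(
    scheme: DecayScheme,
    sphere: Sphere,
    n_histories: int,
    seed: int | None = None,
    keep_per_history: bool = False,
) -> TransportResult:
    """Simulate ``n_histories`` decays uniformly distributed in the sphere.

    All emissions of a decay share the decay site; every transported particle's
    deposit and escape are scored against its history, so per-history energy is
    conserved exactly (deposited + escaped = emitted).
    """
    if not n_histories >= 1:
        raise ValueError("n_histories must be >= 1")
    n = int(n_histories)
    rng = np.random.default_rng(seed)
    radius = sphere.radius_cm
    rho = sphere.density_g_cm3

    pos = _uniform_positions(n, radius, rng)
    hid_all = np.arange(n, dtype=np.intp)

    emit = {c: np.zeros(n) for c in COMPONENTS}
    dep = {c: np.zeros(n) for c in COMPONENTS}
    esc = np.zeros(n)

    # beta continuum
    e_beta = sample_beta_energies(scheme, n, rng)
    dir_beta = _isotropic_directions(n, rng)
    d_beta = _dist_to_boundary(pos, dir_beta, radius)
    dep_beta = _electron_deposit(e_beta, d_beta, rho)
    emit["beta"] += e_beta
    dep["beta"] += dep_beta
    esc += e_beta - dep_beta

    # discrete lines: Bernoulli inclusion with probability = yield
    photon_pos, photon_dir, photon_e, photon_hid = [], [], [], []
    for line in scheme.discrete:
        mask = rng.random(n) < line.yield_per_decay
        m = int(mask.sum())
        if m == 0:
            continue
        dirs = _isotropic_directions(m, rng)
        if line.kind == "electron":
            d_e = _dist_to_boundary(pos[mask], dirs, radius)
            dep_e = _electron_deposit(np.full(m, line.energy_kev), d_e, rho)
            emit["electron"][mask] += line.energy_kev
            dep["electron"][mask] += dep_e
            esc[mask] += line.energy_kev - dep_e
        else:
            emit["photon"][mask] += line.energy_kev
            photon_pos.append(pos[mask])
            photon_dir.append(dirs)
            photon_e.append(np.full(m, line.energy_kev))
            photon_hid.append(hid_all[mask])

    if photon_e:
        dep_ph = np.zeros(n)
        _transport_photon_batch(
            np.concatenate(photon_pos),
            np.concatenate(photon_dir),
            np.concatenate(photon_e),
            np.concatenate(photon_hid),
            sphere,
            rng,
            dep_ph,
            esc,
        )
        dep["photon"] += dep_ph

    emitted = {c: float(emit[c].sum()) for c in COMPONENTS}
    deposited = {c: float(dep[c].sum()) for c in COMPONENTS}
    escaped = float(esc.sum())

    frac = {}
    se = {}
    for c in COMPONENTS:
        if emitted[c] > 0:
            phi = deposited[c] / emitted[c]
            # ratio-estimator standard error of the absorbed fraction
            resid = dep[c] - phi * emit[c]
            se_c = float(np.std(resid, ddof=1) / np.sqrt(n) / (emitted[c] / n))
        else:
            phi, se_c = 0.0, 0.0
        frac[c] = float(min(phi, 1.0))
        se[c] = se_c
    tot_emit = sum(emitted.values())
    tot_dep = sum(deposited.values())
    phi_tot = tot_dep / tot_emit
    emit_all = sum(emit.values())
    dep_all = sum(dep.values())
    resid = dep_all - phi_tot * emit_all
    se_tot = float(np.std(resid, ddof=1) / np.sqrt(n) / (tot_emit / n))

    per_history = None
    if keep_per_history:
        per_history = {f"emitted_{c}": emit[c] for c in COMPONENTS}
        per_history.update({f"deposited_{c}": dep[c] for c in COMPONENTS})
        per_history["escaped"] = esc
        per_history["deposited_total"] = dep_all
        per_history["emitted_total"] = emit_all

    return TransportResult(
        n_histories=n,
        sphere=sphere,
        seed=seed,
        energy_emitted_kev=emitted,
        energy_deposited_kev=deposited,
        energy_escaped_kev=escaped,
        absorbed_fraction=frac,
        absorbed_fraction_total=float(phi_tot),
        mc_standard_error=se,
        mc_standard_error_total=se_tot,
        per_history=per_history,
    )


# ---------------------------------------------------------------------------
# S-values
# ---------------------------------------------------------------------------

def s_value(result: TransportResult, sphere: Sphere) -> SValue:
    """S = (mean deposited energy per decay, J) / (sphere mass, kg)."""
    if result.sphere != sphere:
        raise ValueError("result was computed for a different sphere")
    if result.n_histories < 1:
        raise ValueError("result has no histories")
    mass_kg = sphere.mass_g * 1e-3
    mean_dep_kev = result.total_deposited_kev / result.n_histories
    value = mean_dep_kev * KEV_TO_J / mass_kg
    # uncertainty from the spread of per-history deposits when available,
    # otherwise propagated from the per-component absorbed-fraction errors
    if result.per_history is not None:
        sd = float(np.std(result.per_history["deposited_total"], ddof=1))
        unc_kev = sd / np.sqrt(result.n_histories)
    else:
        unc_kev = np.sqrt(
            sum(
                (result.mc_standard_error[c] * result.energy_emitted_kev[c] / result.n_histories) ** 2
                for c in COMPONENTS
            )
        )
    return SValue(
        value=value,
        uncertainty=float(unc_kev * KEV_TO_J / mass_kg),
        sphere=sphere,
        n_histories=result.n_histories,
        seed=result.seed,
    )


def sweep_svalues(
    scheme: DecayScheme,
    masses_g,
    n_histories: int,
    seed: int | None = None,
) -> list[SValue]:
    """Simulate a list of sphere masses; per-mass seeds derived from ``seed``."""
    out = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(list(masses_g)))]
    for mass, sub in zip(masses_g, child_seeds):
        sphere = Sphere(float(mass))
        res = simulate_sphere(scheme, sphere, n_histories, seed=sub, keep_per_history=True)
        out.append(s_value(res, sphere))
    return out


def load_reference_table(path: str | Path | None = None) -> pd.DataFrame:
    """Reference sphere S-values (columns mass_g, s_gy_per_bq_s, provenance)."""
    if path is None:
        return _read_data_csv("sphere_svalue_reference_synthetic.csv")
    return pd.read_csv(path, comment="#")


def compare_to_reference(
    svalues: list[SValue], reference: pd.DataFrame
) -> float:
    """Max relative deviation |S_mc - S_ref| / S_ref over the simulated masses."""
    ref = dict(zip(reference["mass_g"], reference["s_gy_per_bq_s"]))
    devs = []
    for sv in svalues:
        mass = sv.sphere.mass_g
        match = [m for m in ref if abs(m - mass) <= 1e-9 * max(1.0, mass)]
        if not match:
            raise KeyError(f"mass {mass} g not present in reference table")
        s_ref = ref[match[0]]
        devs.append(abs(sv.value - s_ref) / s_ref)
    return float(max(devs))
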