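"""Two-fidelity poromechanical data generator: a ventilated spherical shell.

The generator solves a spherically symmetric finite-strain poroelastic
boundary-value problem that mirrors the structure of patient-specific lung
models at desk scale.  A thick shell of Blatz-Ko parenchyma (reference radii
``r_inner`` to ``r_outer``, mm) is ventilated through its inner (airway)
surface, where the pressure-controlled ventilation waveform prescribes both
the pore pressure and the total compressive traction.  The outer (pleural)
surface is impermeable and tethered by distributed linear springs of
stiffness ``Ks`` representing the chest wall (a Robin condition).

Governing equations (material form, quasi-static, body forces neglected):

* momentum:  Div P_tot = 0, with the Terzaghi split
  ``P_tot = P_eff(F) - J p_alv F^{-T}``;
* gas mass balance:  ``dJ/dt + Div Q = 0`` with Darcy flux
  ``Q = -k_mob J F^{-1} F^{-T} Grad p_alv``, where ``k_mob`` is the lumped
  mobility (intrinsic permeability over gas viscosity, mm^2/(kPa s)).

Discretization: linear finite elements in the radial coordinate with
two-point Gauss quadrature, backward-Euler time stepping, and a damped
Newton solve of the coupled residual at each step.  The fidelity split is
mesh resolution: the high-fidelity preset uses 64 radial elements and a
2000-point observation cloud, the low-fidelity preset 8 elements and 150
points, so the LF/HF gap is genuine discretization error.

Units: mm, s, kPa internally; ventilator pressures cross the interface in
cmH2O (1 cmH2O = 0.0980665 kPa), volumes are reported in mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pulmoflow.constitutive import (
    MaterialParameters,
    strain_energy_derivatives,
)

__all__ = [
    "CMH2O_TO_KPA",
    "FIDELITY_PRESETS",
    "BASELINE_PARAMETERS",
    "PARAMETER_NAMES",
    "VentilatorWaveform",
    "ParameterVector",
    "ShellMesh",
    "ShellGeometry",
    "RadialSolution",
    "SpatioTemporalResponse",
    "LungSignals",
    "SolverError",
    "StateError",
    "EstimationError",
    "airway_pressure",
    "run_simulation",
    "scatter_observation_nodes",
    "project_to_cloud",
    "compute_signals",
    "estimate_lung_mechanics",
]

CMH2O_TO_KPA = 0.0980665

PARAMETER_NAMES = ("p_pip", "c", "beta", "c1", "c3", "k_mob", "Ks")


class SolverError(RuntimeError):
    """Newton iteration failed to converge at some time step."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class StateError(RuntimeError):
    """A non-physical state (J <= 0 or mesh interpenetration) was produced."""


class EstimationError(ValueError):
    """Least-squares lung-mechanics estimation is ill-posed."""


# --------------------------------------------------------------------------
# ventilator waveform
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VentilatorWaveform:
    """Pressure-controlled ventilation (PCV) airway pressure waveform.

    The pressure ramps linearly from zero to the peak inspiratory pressure
    (PIP) over ``t_ramp`` seconds, holds the plateau until the end of
    inspiration, and is zero throughout expiration.  Defaults give two
    3-second respiratory cycles (1 s inspiration, 2 s expiration; a
    respiratory rate of 20/min) sampled at 120 uniform time steps.
    """

    pip: float  # cmH2O
    t_ramp: float = 0.3
    t_insp: float = 1.0
    t_exp: float = 2.0
    n_cycles: int = 2
    n_steps: int = 120

    def __post_init__(self) -> None:
        if self.pip < 0:
            raise ValueError("PIP must be >= 0")
        if not 0 < self.t_ramp <= self.t_insp:
            raise ValueError("need 0 < t_ramp <= t_insp")
        if self.t_exp <= 0 or self.n_cycles < 1:
            raise ValueError("invalid waveform timing")
        if self.n_steps % self.n_cycles != 0:
            raise ValueError("n_steps must be divisible by n_cycles")

    @property
    def period(self) -> float:
        return self.t_insp + self.t_exp

    @property
    def duration(self) -> float:
        return self.n_cycles * self.period

    @property
    def dt(self) -> float:
        return self.duration / self.n_steps

    @property
    def times(self) -> np.ndarray:
        """Stored time grid: ``t_i = i * dt`` with ``t_0 = 0``."""
        return np.arange(self.n_steps) * self.dt

    def pressure_cmh2o(self, t):
        return airway_pressure(t, self) / CMH2O_TO_KPA

    @property
    def peak_index(self) -> int:
        """Index of the last-cycle end-of-inspiration (peak inflation) instant."""
        t_peak = (self.n_cycles - 1) * self.period + self.t_insp
        return int(round(t_peak / self.dt))


def airway_pressure(t, w: VentilatorWaveform):
    """PCV airway pressure at time(s) ``t`` in kPa.

    Zero at t = 0 and during expiration; linear ramp of duration
    ``w.t_ramp`` up to the PIP plateau.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("airway_pressure requires t >= 0")
    tau = np.mod(t, w.period)
    pip_kpa = w.pip * CMH2O_TO_KPA
    ramp = pip_kpa * tau / w.t_ramp
    plateau = np.full_like(tau, pip_kpa)
    out = np.where(tau < w.t_ramp, ramp, np.where(tau <= w.t_insp, plateau, 0.0))
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# parameters and geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterVector:
    """The 7 sampled simulation inputs xi.

    Fields: ventilator PIP (cmH2O); the four sampled Blatz-Ko constants
    (kPa / dimensionless); Darcy mobility ``k_mob`` (mm^2/(kPa s)); and the
    chest-wall spring stiffness ``Ks`` (kPa/mm).
    """

    p_pip: float
    c: float
    beta: float
    c1: float
    c3: float
    k_mob: float
    Ks: float

    def __post_init__(self) -> None:
        if self.p_pip < 0:
            raise ValueError("p_pip must be >= 0")
        for name in ("c", "beta", "c1", "c3", "k_mob", "Ks"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ParameterVector.{name} must be > 0")

    def material(self) -> MaterialParameters:
        return MaterialParameters(c=self.c, beta=self.beta, c1=self.c1, c3=self.c3)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])

    @classmethod
    def from_array(cls, arr) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError("parameter vector must have 7 entries")
        return cls(**dict(zip(PARAMETER_NAMES, arr)))


#: Baseline parameter values; the sampled space is the +/-50% box around them.
BASELINE_PARAMETERS = ParameterVector(
    p_pip=6.0, c=0.3567, beta=1.075, c1=0.2782, c3=5.766e3, k_mob=1.0e4, Ks=80e-3
)


@dataclass(frozen=True)
class ShellGeometry:
    """Reference shell radii (mm) of one lung analogue."""

    r_inner: float = 5.0
    r_outer: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.r_inner < self.r_outer:
            raise ValueError("need 0 < r_inner < r_outer")

    @property
    def reference_volume_mm3(self) -> float:
        return 4.0 * np.pi / 3.0 * (self.r_outer**3 - self.r_inner**3)


@dataclass(frozen=True)
class ShellMesh:
    """Uniform linear-element discretization of the reference shell."""

    geometry: ShellGeometry
    n_el: int

    def __post_init__(self) -> None:
        if self.n_el < 2:
            raise ValueError("n_el must be >= 2")

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.geometry.r_inner, self.geometry.r_outer, self.n_el + 1)


@dataclass(frozen=True)
class FidelityPreset:
    n_el: int
    cloud_size: int


FIDELITY_PRESETS = {
    "H": FidelityPreset(n_el=64, cloud_size=2000),
    "L": FidelityPreset(n_el=8, cloud_size=150),
}


# --------------------------------------------------------------------------
# solution containers
# --------------------------------------------------------------------------


@dataclass
class RadialSolution:
    """Nodal radial solution of one simulation.

    ``phi`` and ``p_alv`` have shape (T, n_nodes); row 0 is the reference
    state at t = 0.  ``volume_ml`` is the quadrature lung volume change and
    ``influx_ml_s`` the backward-Euler-consistent inlet gas influx over each
    step (both in mL / mL/s), satisfying the discrete mass balance
    ``(V_k - V_{k-1}) / dt = influx_k`` to solver tolerance.
    """

    mesh: ShellMesh
    waveform: VentilatorWaveform
    times: np.ndarray
    phi: np.ndarray
    p_alv: np.ndarray
    volume_ml: np.ndarray
    influx_ml_s: np.ndarray
    newton_iters: np.ndarray

    @property
    def displacement(self) -> np.ndarray:
        """Radial displacement u_r(R, t), shape (T, n_nodes), mm."""
        return self.phi - self.mesh.nodes[None, :]


@dataclass
class SpatioTemporalResponse:
    """Four fields on K observation nodes over T stored steps."""

    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray
    palv: np.ndarray
    cloud: np.ndarray
    times: np.ndarray
    fidelity: str

    def field(self, quantity: str) -> np.ndarray:
        return {"ux": self.ux, "uy": self.uy, "uz": self.uz, "palv": self.palv}[quantity]

    @property
    def K(self) -> int:
        return self.cloud.shape[0]

    @property
    def T(self) -> int:
        return self.times.size


@dataclass
class LungSignals:
    """Global respiratory signals post-processed from one simulation."""

    times: np.ndarray
    paw_cmh2o: np.ndarray
    volume_ml: np.ndarray
    flow_ml_s: np.ndarray
    v0_ml: float


# --------------------------------------------------------------------------
# residual assembly
# --------------------------------------------------------------------------

_GAUSS_XI = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
_GAUSS_W = np.array([0.5, 0.5])  # weights on the unit interval


class _Discretization:
    """Precomputed mesh/quadrature data shared across residual evaluations."""

    def __init__(self, mesh: ShellMesh):
        self.mesh = mesh
        R = mesh.nodes
        self.R = R
        self.n = R.size
        self.h = np.diff(R)  # (n_el,)
        # Gauss-point reference radii and shape functions, shape (n_el, 2)
        self.Rg = R[:-1, None] + _GAUSS_XI[None, :] * self.h[:, None]
        self.N1 = 1.0 - _GAUSS_XI
        self.N2 = _GAUSS_XI
        # integration weight: w * (h/2)*2 ... weights already on unit interval
        self.wq = _GAUSS_W[None, :] * self.h[:, None]  # (n_el, 2)
        self.area = 4.0 * np.pi * self.Rg**2

    def at_gauss(self, nodal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Value and radial derivative of a nodal field at Gauss points."""
        a, b = nodal[:-1, None], nodal[1:, None]
        val = a * self.N1[None, :] + b * self.N2[None, :]
        grad = (b - a) / self.h[:, None]
        return val, grad

    def jacobian_field(self, phi: np.ndarray) -> np.ndarray:
        """Deformation Jacobian J at Gauss points, shape (n_el, 2)."""
        phig, lr = self.at_gauss(phi)
        lt = phig / self.Rg
        return lr * lt**2

    def volume_change_mm3(self, phi: np.ndarray) -> float:
        """Quadrature of (J - 1) over the reference shell."""
        return float(np.sum(self.wq * self.area * (self.jacobian_field(phi) - 1.0)))

    def scatter(self, gp_vals: np.ndarray) -> np.ndarray:
        """Assemble Gauss-point integrand (already weighted) to nodes."""
        out = np.zeros(self.n)
        np.add.at(out, np.arange(self.n - 1), gp_vals @ self.N1)
        np.add.at(out, np.arange(1, self.n), gp_vals @ self.N2)
        return out


def _assemble_residual(disc, phi, p, J_prev_gp, dt, mat, xi, pbar_kpa):
    """Raw (unscaled) residual blocks of the coupled backward-Euler system.

    Returns (momentum residual, mass residual) per node; the mass residual
    at the inner node equals the inlet boundary influx (mm^3/s) when the
    interior equations are satisfied, and the Dirichlet replacement is
    applied by the caller.
    """
    phig, lr = disc.at_gauss(phi)
    pg, dp = disc.at_gauss(p)
    if np.any(lr <= 1e-12) or np.any(phig <= 1e-12):
        raise FloatingPointError("non-physical trial state")
    lt = phig / disc.Rg
    J = lr * lt**2

    I1 = lr**2 + 2.0 * lt**2
    I3 = J**2
    W1, W3 = strain_energy_derivatives(I1, I3, mat)
    Pr = 2.0 * lr * (W1 + W3 * lt**4) - pg * lt**2
    Pt = 2.0 * lt * (W1 + W3 * lr**2 * lt**2) - pg * lr * lt

    wA = disc.wq * disc.area
    # momentum: integrand_a = Pr * dN_a/dR + 2 Pt * N_a / R
    hoop = wA * 2.0 * Pt / disc.Rg
    rad = wA * Pr / disc.h[:, None]
    f_mom = np.zeros(disc.n)
    np.add.at(f_mom, np.arange(disc.n - 1), (hoop * disc.N1[None, :]).sum(1) - rad.sum(1))
    np.add.at(f_mom, np.arange(1, disc.n), (hoop * disc.N2[None, :]).sum(1) + rad.sum(1))
    # follower airway pressure on the current inner surface
    f_mom[0] -= pbar_kpa * 4.0 * np.pi * phi[0] ** 2
    # chest-wall spring (material Robin condition, restoring)
    Rb = disc.R[-1]
    f_mom[-1] += xi.Ks * (phi[-1] - Rb) * 4.0 * np.pi * Rb**2

    # mass: integrand_a = (J - J_prev)/dt * N_a + k_mob (lt^2/lr) p' * dN_a/dR
    storage = wA * (J - J_prev_gp) / dt
    darcy = wA * xi.k_mob * (lt**2 / lr) * dp / disc.h[:, None]
    f_mass = np.zeros(disc.n)
    np.add.at(f_mass, np.arange(disc.n - 1), (storage * disc.N1[None, :]).sum(1) - darcy.sum(1))
    np.add.at(f_mass, np.arange(1, disc.n), (storage * disc.N2[None, :]).sum(1) + darcy.sum(1))
    return f_mom, f_mass


class _StepSolver:
    """Damped Newton solver for one backward-Euler step on a fixed mesh."""

    max_iter = 25
    rtol = 1e-9
    atol = 1e-10

    def __init__(self, disc: _Discretization, mat: MaterialParameters, xi: ParameterVector):
        self.disc = disc
        self.mat = mat
        self.xi = xi
        n = disc.n
        self.n = n
        pip_kpa = max(xi.p_pip * CMH2O_TO_KPA, 1e-3)
        geo = disc.mesh.geometry
        a_out = 4.0 * np.pi * geo.r_outer**2
        self.p_scale = pip_kpa
        self.mom_scale = a_out * (mat.c + pip_kpa)
        self.mass_scale = a_out * xi.k_mob * pip_kpa / (geo.r_outer - geo.r_inner)
        self.eps_phi = 1e-7 * geo.r_outer
        self.eps_p = 1e-7 * self.p_scale
        # FD-Jacobian colouring: with linear elements node i only couples to
        # nodes i-1..i+1, so perturbing every third node is unambiguous.
        self._colors = [np.arange(c, n, 3) for c in range(3)]

    def scaled_residual(self, z, J_prev_gp, dt, pbar):
        phi, p = z[: self.n], z[self.n :]
        f_mom, f_mass = _assemble_residual(
            self.disc, phi, p, J_prev_gp, dt, self.mat, self.xi, pbar
        )
        F = np.empty(2 * self.n)
        F[: self.n] = f_mom / self.mom_scale
        F[self.n :] = f_mass / self.mass_scale
        F[self.n] = (p[0] - pbar) / self.p_scale  # Dirichlet: p(r_inner) = Pbar(t)
        return F

    def _fd_jacobian(self, z, F0, J_prev_gp, dt, pbar):
        n = self.n
        J = np.zeros((2 * n, 2 * n))
        for block, eps in ((0, self.eps_phi), (1, self.eps_p)):
            for idx in self._colors:
                cols = block * n + idx
                zp = z.copy()
                zp[cols] += eps
                dF = (self.scaled_residual(zp, J_prev_gp, dt, pbar) - F0) / eps
                for i in idx:
                    lo, hi = max(i - 1, 0), min(i + 1, n - 1)
                    rows = np.r_[lo : hi + 1, n + lo : n + hi + 1]
                    J[rows, block * n + i] = dF[rows]
        return J

    def solve_step(self, z_prev, dt, pbar, step_index, depth=0):
        """Advance one step; on Newton failure, bisect the step in time."""
        J_prev_gp = self.disc.jacobian_field(z_prev[: self.n])
        z = z_prev.copy()
        z[self.n] = pbar  # consistent Dirichlet start
        F = self.scaled_residual(z, J_prev_gp, dt, pbar)
        f0 = np.max(np.abs(F))
        tol = max(self.atol, self.rtol * f0)
        influx = None
        converged = f0 <= self.atol
        it = 0
        while not converged and it < self.max_iter:
            Jmat = self._fd_jacobian(z, F, J_prev_gp, dt, pbar)
            try:
                dz = np.linalg.solve(Jmat, -F)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SolverError(f"singular Jacobian at step {step_index}", step_index) from exc
            fn = np.max(np.abs(F))
            alpha = 1.0
            for _ in range(12):
                try:
                    F_new = self.scaled_residual(z + alpha * dz, J_prev_gp, dt, pbar)
                except FloatingPointError:
                    alpha *= 0.5
                    continue
                if np.max(np.abs(F_new)) < fn or alpha < 1e-3:
                    break
                alpha *= 0.5
            else:
                break  # no acceptable step: fall through to substepping
            z = z + alpha * dz
            F = F_new
            it += 1
            converged = np.max(np.abs(F)) <= tol
        if not converged:
            if depth >= 5:
                raise SolverError(
                    f"Newton did not converge at step {step_index}", step_index
                )
            return self._substep(z_prev, dt, pbar, step_index, depth)
        influx = self._influx(z, J_prev_gp, dt, pbar)
        self._check_state(z)
        return z, influx, it

    def _substep(self, z_prev, dt, pbar, step_index, depth):
        # bisect in time, holding the end-of-step boundary pressure: the
        # backward-Euler target state is unchanged, only the path is split
        z_mid, inf1, it1 = self.solve_step(z_prev, dt / 2, pbar, step_index, depth + 1)
        z_end, inf2, it2 = self.solve_step(z_mid, dt / 2, pbar, step_index, depth + 1)
        return z_end, 0.5 * (inf1 + inf2), max(it1, it2)

    def _influx(self, z, J_prev_gp, dt, pbar):
        """Reaction flux at the constrained inner node (mm^3/s)."""
        _, f_mass = _assemble_residual(
            self.disc, z[: self.n], z[self.n :], J_prev_gp, dt, self.mat, self.xi, pbar
        )
        return float(f_mass[0])

    def _check_state(self, z):
        phi = z[: self.n]
        if np.any(np.diff(phi) <= 0):
            raise StateError("mesh interpenetration: phi not increasing in R")
        if np.any(self.disc.jacobian_field(phi) <= 0):
            raise StateError("non-positive Jacobian J")


# --------------------------------------------------------------------------
# public simulation driver
# --------------------------------------------------------------------------


def run_simulation(
    xi: ParameterVector,
    fidelity: str = "H",
    *,
    geometry: ShellGeometry | None = None,
    mesh: ShellMesh | None = None,
    cloud: np.ndarray | None = None,
    cloud_size: int | None = None,
    cloud_seed: int = 0,
    waveform: VentilatorWaveform | None = None,
) -> tuple[RadialSolution, SpatioTemporalResponse]:
    """Run one ventilated-shell simulation and project it to a node cloud.

    Parameters
    ----------
    xi : ParameterVector
        The 7 sampled inputs.
    fidelity : {"H", "L"}
        Selects the mesh/cloud preset (HF: 64 elements, 2000 cloud nodes;
        LF: 8 elements, 150 nodes) unless ``mesh``/``cloud`` override it.
    cloud : (K, 3) array, optional
        Observation nodes; generated from ``cloud_seed`` when omitted.
        Training datasets must reuse one cloud across all runs of a
        fidelity so that output-matrix columns are comparable.
    waveform : VentilatorWaveform, optional
        Defaults to the PCV waveform at ``xi.p_pip``.

    Returns
    -------
    (RadialSolution, SpatioTemporalResponse)
    """
    if fidelity not in FIDELITY_PRESETS:
        raise ValueError("fidelity must be 'H' or 'L'")
    preset = FIDELITY_PRESETS[fidelity]
    geometry = geometry or ShellGeometry()
    if mesh is None:
        mesh = ShellMesh(geometry=geometry, n_el=preset.n_el)
    else:
        geometry = mesh.geometry
    if cloud is None:
        cloud = scatter_observation_nodes(
            cloud_size or preset.cloud_size, geometry.r_inner, geometry.r_outer, cloud_seed
        )
    if waveform is None:
        waveform = VentilatorWaveform(pip=xi.p_pip)

    disc = _Discretization(mesh)
    solver = _StepSolver(disc, xi.material(), xi)
    n = disc.n
    times = waveform.times
    T = times.size
    dt = waveform.dt

    phi = np.empty((T, n))
    p = np.empty((T, n))
    vol = np.empty(T)
    influx = np.zeros(T)
    iters = np.zeros(T, dtype=int)

    z = np.concatenate([mesh.nodes, np.zeros(n)])
    phi[0], p[0] = z[:n], z[n:]
    vol[0] = 0.0
    for k in range(1, T):
        pbar = float(airway_pressure(times[k], waveform))
        z, influx_k, it = solver.solve_step(z, dt, pbar, k)
        phi[k], p[k] = z[:n], z[n:]
        vol[k] = disc.volume_change_mm3(z[:n])
        influx[k] = influx_k
        iters[k] = it

    sol = RadialSolution(
        mesh=mesh,
        waveform=waveform,
        times=times,
        phi=phi,
        p_alv=p,
        volume_ml=vol / 1000.0,
        influx_ml_s=influx / 1000.0,
        newton_iters=iters,
    )
    response = project_to_cloud(sol, cloud, fidelity=fidelity)
    return sol, response


def scatter_observation_nodes(n: int, r_inner: float, r_outer: float, seed: int) -> np.ndarray:
    """Sample ``n`` observation nodes uniformly in the shell volume.

    Radii follow the r^3 volume law; directions are isotropic.  The result
    is deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    r = (r_inner**3 + u * (r_outer**3 - r_inner**3)) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * r[:, None]


def project_to_cloud(
    sol: RadialSolution, cloud: np.ndarray, fidelity: str = "H"
) -> SpatioTemporalResponse:
    """Interpolate the radial solution onto a 3D observation-node cloud.

    At a node with reference position ``x`` and radius ``r``, the
    displacement is ``u_r(r, t) * x / r`` and the alveolar pressure is the
    interpolated nodal pore pressure.  Piecewise-linear interpolation on
    the mesh nodes reproduces nodal values exactly and is monotone.
    """
    cloud = np.asarray(cloud, dtype=float)
    radii = np.linalg.norm(cloud, axis=1)
    R = sol.mesh.nodes
    tol = 1e-9 * R[-1]
    if np.any(radii < R[0] - tol) or np.any(radii > R[-1] + tol):
        raise ValueError("cloud radii outside the mesh range (extrapolation refused)")
    radii = np.clip(radii, R[0], R[-1])
    T = sol.times.size
    K = cloud.shape[0]
    u_hat = cloud / radii[:, None]
    ux = np.empty((K, T))
    uy = np.empty((K, T))
    uz = np.empty((K, T))
    palv = np.empty((K, T))
    disp = sol.displacement
    for k in range(T):
        ur = np.interp(radii, R, disp[k])
        ux[:, k] = ur * u_hat[:, 0]
        uy[:, k] = ur * u_hat[:, 1]
        uz[:, k] = ur * u_hat[:, 2]
        palv[:, k] = np.interp(radii, R, sol.p_alv[k])
    return SpatioTemporalResponse(
        ux=ux, uy=uy, uz=uz, palv=palv, cloud=cloud, times=sol.times.copy(), fidelity=fidelity
    )


def compute_signals(sol: RadialSolution, w: VentilatorWaveform | None = None) -> LungSignals:
    """Global lung signals: airway pressure, tidal volume, and flow.

    Volume is the quadrature of (J - 1) over the reference shell (mL);
    flow is its centred finite-difference time derivative (mL/s); the
    airway pressure is the prescribed waveform (cmH2O).
    """
    w = w or sol.waveform
    flow = np.gradient(sol.volume_ml, w.dt)
    paw = np.asarray(w.pressure_cmh2o(sol.times), dtype=float)
    v0 = sol.mesh.geometry.reference_volume_mm3 / 1000.0
    return LungSignals(
        times=sol.times.copy(),
        paw_cmh2o=paw,
        volume_ml=sol.volume_ml.copy(),
        flow_ml_s=flow,
        v0_ml=v0,
    )


def estimate_lung_mechanics(sig: LungSignals) -> tuple[float, float]:
    """Least-squares single-compartment lung mechanics (Crs, R).

    Fits the equation of motion ``Paw = V / Crs + R * dV/dt + P0`` by
    ordinary least squares over all samples.  Returns compliance Crs
    (mL/cmH2O) and resistance R (cmH2O s/mL).
    """
    X = np.column_stack([sig.volume_ml, sig.flow_ml_s, np.ones_like(sig.volume_ml)])
    if np.linalg.matrix_rank(X) < 3:
        raise EstimationError("rank-deficient design: signals do not identify Crs and R")
    coef, *_ = np.linalg.lstsq(X, sig.paw_cmh2o, rcond=None)
    elastance = coef[0]
    if elastance == 0:
        raise EstimationError("zero estimated elastance")
    return 1.0 / elastance, float(coef[1])
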