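"""Overdamped Langevin surrogate for field-driven channel permeation.

The nonequilibrium "passing-through" protocol is modelled at desk scale:
a charged permeant moves in one dimension along the channel axis under a
Gaussian free-energy barrier at the ring plane and a constant external
electric field (EEF) applied to the permeant only.  The axial coordinate
obeys the Euler–Maruyama discretization of

    dz = (F/γ)·dt + √(2 k_B T dt / γ)·ξ,   F = q·E·C − dU/dz,

with the unit conversion C = 23.0605 kcal/(mol·Å) per e·(Volt/Å), so that
fields quoted in Volt/Å act directly in kcal/mol energetics.  The channel
mouths reflect the permeant until it has crossed the ring plane, after
which reaching a mouth counts as a completed exit and the permeant is
re-inserted at the opposite mouth for the next attempt.  This surrogate
reproduces the protocol's logic (field on the permeant only, EEF
titration, per-run event counting), not any particular all-atom result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import AtomRecord, StructureFrame, Trajectory
from .energetics import EV_PER_ANGSTROM_TO_KCAL
from .passage import DEFAULT_HYSTERESIS, PassageTrace, count_passages

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "PermeationConfig",
    "PermeationResult",
    "simulate_permeation",
    "titrate_eef",
]

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_PER_MOL_K = 0.0019872041


@dataclass(frozen=True)
class PermeationConfig:
    """Parameters of the 1-D permeation surrogate.

    ``eef`` is the external field in Volt/Å (applied to the permeant
    only); ``charge`` the permeant charge in e; ``friction`` γ in
    kcal·ps/(mol·Å²); the Gaussian barrier sits at the ring plane z = 0
    with height in kcal/mol and width (standard deviation) in Å; the
    channel spans ±``channel_half_length`` Å.  Lateral confinement is
    folded into the effective barrier, so the dynamics are purely axial.
    """

    eef: float = 0.2
    charge: float = 1.0
    friction: float = 15.0
    temperature: float = 298.0
    barrier_height: float = 3.0
    barrier_width: float = 3.0
    channel_half_length: float = 20.0
    dt_ps: float = 0.02
    duration_ns: float = 5.0
    sample_every: int = 25
    start_z: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.friction <= 0 or self.dt_ps <= 0 or self.duration_ns <= 0:
            raise ValueError("friction, dt and duration must be positive")
        if self.barrier_width <= 0 or self.channel_half_length <= 0:
            raise ValueError("barrier width and channel length must be positive")
        if abs(self.start_z) > self.channel_half_length:
            raise ValueError("start_z must lie inside the channel")

    @property
    def field_force(self) -> float:
        """q·E·C in kcal/(mol·Å)."""
        return self.charge * self.eef * EV_PER_ANGSTROM_TO_KCAL


@dataclass
class PermeationResult:
    """Sampled axial trace plus exit bookkeeping for one run."""

    times_ns: np.ndarray
    z: np.ndarray
    n_exits: int
    net_displacement: float
    config: PermeationConfig

    def to_passage_trace(self, ring_z: float = 0.0) -> PassageTrace:
        offset = self.z - ring_z
        return PassageTrace(
            times_ns=self.times_ns, offset=offset, distance=np.abs(offset)
        )

    def to_trajectory(self) -> Trajectory:
        frames = []
        for t, z in zip(self.times_ns, self.z):
            atom = AtomRecord(
                atom_name="DHS",
                element="C",
                chain_id="X",
                residue_local_index=1,
                residue_name="DHS",
                coords=np.array([0.0, 0.0, z]),
            )
            frames.append(StructureFrame([atom], time_ns=float(t)))
        return Trajectory(frames)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ns": self.times_ns, "z_A": self.z, "distance_A": np.abs(self.z)}
        )


def simulate_permeation(config: PermeationConfig) -> PermeationResult:
    """Run one seeded Euler–Maruyama permeation trajectory.

    Raises a stability error when the largest drift displacement per step
    exceeds the barrier width (the integrator would step over the barrier).
    """
    gamma = config.friction
    dt = config.dt_ps
    f_field = config.field_force
    h, w, L = config.barrier_height, config.barrier_width, config.channel_half_length
    max_slope = h / (w * np.sqrt(np.e))  # max |dU/dz| of the Gaussian barrier
    if (abs(f_field) + max_slope) / gamma * dt > w:
        raise ValueError(
            "dt too large: drift per step exceeds the barrier width; reduce dt_ps"
        )
    n_steps = int(round(config.duration_ns * 1000.0 / dt))
    sigma = np.sqrt(2.0 * KB_KCAL_PER_MOL_K * config.temperature * dt / gamma)
    rng = np.random.default_rng(config.seed)

    z = float(config.start_z)
    crossed = False
    n_exits = 0
    disp = 0.0
    n_samples = n_steps // config.sample_every + 1
    zs = np.empty(n_samples)
    ts = np.empty(n_samples)
    zs[0], ts[0] = z, 0.0
    ptr = 1
    inv_w2 = 1.0 / (w * w)
    chunk = 65536
    noise = rng.standard_normal(min(chunk, n_steps)) * sigma
    noise_i = 0
    for step in range(1, n_steps + 1):
        if noise_i >= noise.size:
            noise = rng.standard_normal(min(chunk, n_steps - step + 1)) * sigma
            noise_i = 0
        # F = qEC - dU/dz with U = h exp(-z^2 / 2 w^2)
        force = f_field + h * z * inv_w2 * np.exp(-0.5 * z * z * inv_w2)
        z_new = z + force / gamma * dt + noise[noise_i]
        noise_i += 1
        if (z > 0.0) != (z_new > 0.0):
            crossed = True
        dz = z_new - z
        if z_new > L or z_new < -L:
            if crossed:
                n_exits += 1
                side = 1.0 if z_new > L else -1.0
                dz = (side * L) - z  # physical part of the step up to the mouth
                z_new = -side * L  # re-insert at the opposite mouth (teleport)
                crossed = False
            else:
                z_new = 2.0 * L - z_new if z_new > L else -2.0 * L - z_new
                dz = z_new - z
        disp += dz
        z = z_new
        if step % config.sample_every == 0:
            zs[ptr] = z
            ts[ptr] = step * dt / 1000.0
            ptr += 1
    return PermeationResult(
        times_ns=ts[:ptr],
        z=zs[:ptr],
        n_exits=n_exits,
        net_displacement=float(disp),
        config=config,
    )


def titrate_eef(
    base: PermeationConfig,
    eef_values: list[float],
    n_runs: int = 4,
    seed: int = 0,
    hysteresis: float = DEFAULT_HYSTERESIS,
) -> pd.DataFrame:
    """Event statistics over an EEF grid (the field-titration protocol).

    Runs ``n_runs`` independently seeded simulations per field value,
    counts passage events on each axial trace with the standard hysteresis
    detector, and tabulates per-run counts, their mean and the success
    fraction (a run is successful iff it has at least one event).
    Duplicate field values pool their runs into a single row.
    """
    if len(eef_values) < 2:
        raise ValueError("need at least 2 EEF values to titrate")
    pooled: dict[float, int] = {}
    for e in eef_values:
        pooled[float(e)] = pooled.get(float(e), 0) + n_runs
    ss = np.random.SeedSequence(seed)
    rows = []
    for eef in sorted(pooled):
        runs = pooled[eef]
        child_seeds = ss.spawn(runs)
        counts = []
        for cs in child_seeds:
            run_seed = int(cs.generate_state(1)[0] % (2**31))
            cfg = replace(base, eef=eef, seed=run_seed)
            res = simulate_permeation(cfg)
            n, _ = count_passages(res.to_passage_trace(), hysteresis=hysteresis)
            counts.append(n)
        counts = np.asarray(counts)
        rows.append(
            {
                "eef_V_per_A": eef,
                "n_runs": runs,
                "events_per_run": list(map(int, counts)),
                "mean_events": float(counts.mean()),
                "success_fraction": float((counts >= 1).mean()),
            }
        )
    return pd.DataFrame(rows)
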