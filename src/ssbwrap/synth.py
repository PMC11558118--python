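"""Synthetic telegraph-trace generator with Bell-model force-dependent rates.

Stands in for the magnetic-tweezers recordings: a continuous-time two-state
Markov chain with

    k_bind(F)   = k_bind0   * exp(-F dx_bind / k_BT)
    k_unbind(F) = k_unbind0 * exp(+F dx_unbind / k_BT)

sampled on a uniform grid with Gaussian measurement noise.  The two
extension levels are force-dependent: the unbound level sits one WLC
extension of the released segment above the bound level, so segmentation
difficulty varies with force as in real recordings.

The shipped condition fixtures encode the experimental ladder: critical
forces of 15 pN (20 mM NaCl), 10 and 15 pN in equal mixture (42 mM), and
7 pN (75 mM), at 10 nM ligand, 100 Hz sampling, 5 nm noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import ForceExtensionTrace
from .polymer import WLCParams, delta_delta_g, wlc_extension
from .thermo import binding_free_energy

__all__ = [
    "BellMode",
    "ConditionSpec",
    "TraceBundle",
    "FIXTURES",
    "condition_fixture",
    "make_telegraph_trace",
    "make_condition_dataset",
]


@dataclass(frozen=True)
class BellMode:
    """Bell-model parameter set for one interaction mode.

    ``k_bind0`` already contains the ligand concentration ([L] k+ at F = 0).
    """

    k_bind0: float  # 1/s
    k_unbind0: float  # 1/s
    dx_bind: float = 1.0  # nm
    dx_unbind: float = 1.0  # nm

    def rates(self, force: float, kt: float) -> tuple[float, float]:
        kb = self.k_bind0 * np.exp(-force * self.dx_bind / kt)
        ku = self.k_unbind0 * np.exp(+force * self.dx_unbind / kt)
        return kb, ku

    def crossover(self, kt: float) -> float:
        """Analytic F_c solving k_bind(F) = k_unbind(F)."""
        return kt * np.log(self.k_bind0 / self.k_unbind0) / (self.dx_bind + self.dx_unbind)

    @classmethod
    def from_crossover(
        cls,
        f_c: float,
        k_at_crossover: float = 1.0,
        dx_bind: float = 1.0,
        dx_unbind: float = 1.0,
        kt: float = 4.1419464,
    ) -> "BellMode":
        """Construct a mode whose rates equal ``k_at_crossover`` at ``f_c``."""
        return cls(
            k_bind0=k_at_crossover * np.exp(f_c * dx_bind / kt),
            k_unbind0=k_at_crossover * np.exp(-f_c * dx_unbind / kt),
            dx_bind=dx_bind,
            dx_unbind=dx_unbind,
        )


@dataclass(frozen=True)
class ConditionSpec:
    """Everything needed to emulate one salt condition."""

    label: str
    salt_mM: float
    ligand_nM: float = 10.0
    modes: tuple[BellMode, ...] = ()
    weights: tuple[float, ...] = (1.0,)
    baseline_nm: float = 600.0  # bound-state extension level
    noise_sd_nm: float = 5.0
    sampling_rate_hz: float = 100.0
    n_released_nt: int = 20
    forces_pN: tuple[float, ...] = ()
    wlc: WLCParams = field(default_factory=WLCParams)

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("at least one Bell mode required")
        if len(self.weights) != len(self.modes):
            raise ValueError("weights and modes must align")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        for m in self.modes:
            if m.k_bind0 <= 0 or m.k_unbind0 <= 0:
                raise ValueError("rates must be > 0")

    def crossovers(self) -> np.ndarray:
        """Generator-truth critical forces, ascending (pN)."""
        return np.sort([m.crossover(self.wlc.kt) for m in self.modes])

    def delta_g0_truth(self) -> np.ndarray:
        """Generator-truth dG0 per mode, ordered like :meth:`crossovers` (k_BT)."""
        return np.array(
            [binding_free_energy(fc, self.n_released_nt, self.wlc) for fc in self.crossovers()]
        )

    def extension_jump(self, force: float) -> float:
        """Unbound-minus-bound extension level at ``force`` (nm)."""
        z = wlc_extension(force, self.wlc)
        return self.n_released_nt * self.wlc.contour_length_per_nt * z


def _default_fixtures() -> dict[str, ConditionSpec]:
    kt = WLCParams().kt
    mk = lambda fc: BellMode.from_crossover(fc, k_at_crossover=1.0, kt=kt)
    return {
        "20mM": ConditionSpec(
            label="fixture_20mM",
            salt_mM=20.0,
            modes=(mk(15.0),),
            weights=(1.0,),
            forces_pN=tuple(np.linspace(12.0, 18.0, 6)),
        ),
        "42mM": ConditionSpec(
            label="fixture_42mM",
            salt_mM=42.0,
            modes=(mk(10.0), mk(15.0)),
            weights=(0.5, 0.5),
            forces_pN=tuple(np.linspace(8.0, 17.0, 7)),
        ),
        "75mM": ConditionSpec(
            label="fixture_75mM",
            salt_mM=75.0,
            modes=(mk(7.0),),
            weights=(1.0,),
            forces_pN=tuple(np.linspace(4.0, 10.0, 6)),
        ),
    }


#: Shipped per-salt condition fixtures (critical forces 15, {10, 15}, 7 pN).
FIXTURES: dict[str, ConditionSpec] = _default_fixtures()


def condition_fixture(name: str, **overrides) -> ConditionSpec:
    """A copy of a shipped fixture, optionally with fields overridden."""
    spec = FIXTURES[name]
    return replace(spec, **overrides) if overrides else spec


def make_telegraph_trace(
    spec: ConditionSpec,
    force: float,
    duration: float,
    seed: int,
    mode_index: int = 0,
) -> tuple[ForceExtensionTrace, np.ndarray]:
    """Simulate one constant-force trace; returns (trace, true state labels).

    The hidden chain is simulated in continuous time (exact exponential
    waiting times) starting from its stationary distribution, then sampled
    at the grid instants; labels are 0 = bound, 1 = unbound.
    """
    rng = np.random.default_rng(seed)
    mode = spec.modes[mode_index]
    kt = spec.wlc.kt
    kb, ku = mode.rates(force, kt)
    if duration * min(kb, ku) < 0.5:
        import warnings

        warnings.warn(
            f"expected < 1 transition in {duration} s at {force} pN", stacklevel=2
        )
    n = int(round(duration * spec.sampling_rate_hz))
    t_grid = np.arange(n) / spec.sampling_rate_hz

    # continuous-time telegraph: switch times until the horizon
    state = 1 if rng.random() < ku / (kb + ku) else 0  # stationary start
    switch_times = []
    switch_states = [state]
    t = 0.0
    while True:
        rate = ku if state == 0 else kb  # leaving-rate of current state
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        switch_times.append(t)
        state = 1 - state
        switch_states.append(state)
    labels = np.asarray(switch_states, dtype=np.int8)[
        np.searchsorted(switch_times, t_grid, side="right")
    ]

    jump = spec.extension_jump(force)
    ext = spec.baseline_nm + jump * labels + rng.normal(0.0, spec.noise_sd_nm, n)
    trace = ForceExtensionTrace(
        time=t_grid,
        extension=ext,
        force=force,
        sampling_rate=spec.sampling_rate_hz,
        condition_label=spec.label,
    )
    return trace, labels


@dataclass
class TraceBundle:
    """A condition dataset plus its generator-truth record."""

    spec: ConditionSpec
    traces: list[ForceExtensionTrace]
    labels: list[np.ndarray]  # generator-truth states per trace
    trace_modes: np.ndarray  # mode index per trace
    seed: int

    @property
    def truth(self) -> dict:
        fc = self.spec.crossovers()
        dg0 = self.spec.delta_g0_truth()
        return {
            "f_c_pN": fc.tolist(),
            "delta_g0_kT": dg0.tolist(),
            "ddg_at_fc_kT": [
                delta_delta_g(f, self.spec.n_released_nt, self.spec.wlc).delta_delta_g
                for f in fc
            ],
        }


def make_condition_dataset(
    spec: ConditionSpec,
    forces: tuple[float, ...] | None = None,
    n_traces: int = 20,
    duration: float = 200.0,
    seed: int = 1,
) -> TraceBundle:
    """Traces at every force of the condition, modes drawn by weight."""
    forces = tuple(forces if forces is not None else spec.forces_pN)
    if not forces:
        raise ValueError("no forces given")
    fc = spec.crossovers()
    if not (min(forces) <= fc.min() and fc.max() <= max(forces)):
        import warnings

        warnings.warn("forces do not bracket the generator crossover(s)", stacklevel=2)
    ss = np.random.SeedSequence(seed)
    mode_rng = np.random.default_rng(ss.spawn(1)[0])
    traces: list[ForceExtensionTrace] = []
    labels: list[np.ndarray] = []
    modes = []
    child_seeds = ss.generate_state(len(forces) * n_traces) % (2**31)
    i = 0
    for force in forces:
        for _ in range(n_traces):
            m = int(mode_rng.choice(len(spec.modes), p=spec.weights))
            tr, lab = make_telegraph_trace(
                spec, float(force), duration, int(child_seeds[i]), mode_index=m
            )
            traces.append(tr)
            labels.append(lab)
            modes.append(m)
            i += 1
    return TraceBundle(
        spec=spec, traces=traces, labels=labels, trace_modes=np.array(modes), seed=seed
    )
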