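"""Config-driven assembly and execution of whole-model scenarios.

A Protocol is an ordered list of environment visits (phases) with dwell
times, run on one continuous trajectory so the true HD at the end of one
environment is the starting HD in the next.  Each simulation step advances
the trajectory and cue dynamics, renders the feature channels, steps the
landmark-bearing (aLB) layer with plasticity, and - unless the protocol is
sensor-only - steps the attractor / gRSC / dRSC loop with Hebbian plasticity
and corrective feedback.  Testing phases freeze all weights and sweep a slow
uniform rotation so every HD is sampled equally.

Two model variants are provided: the full two-stage model (visual -> aLB ->
dRSC) and a 'direct' alternative in which the aLB layer is removed and the
visual channels project straight onto dRSC through classic Hebbian weights.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .alb import AlbLayer, AlbParams
from .analysis import RepresentationMap, build_representation
from .config import ModelConfig, default_config
from .hd_circuit import Attractor, RscLoop, RscWeights, calibrate_velocity_gain
from .trajectory import Trajectory, synth_trajectory, test_rotation
from .world import Cue, CueDynamics, Environment, advance_cues, channel_response, wrap_deg

__all__ = [
    "Phase",
    "Protocol",
    "RunResult",
    "HDNetwork",
    "run_protocol",
    "scenario_library",
    "list_scenarios",
    "assemble_direct_model",
]

# velocity-gain calibrations are deterministic per attractor spec; cache them
_GAIN_CACHE: dict[tuple, float] = {}


def _calibrated(spec, dt: float):
    key = (
        spec.n,
        spec.kappa,
        spec.amp,
        spec.inhibition,
        spec.tau,
        spec.transfer.alpha,
        spec.transfer.beta,
        round(dt, 9),
    )
    if key not in _GAIN_CACHE:
        _GAIN_CACHE[key] = calibrate_velocity_gain(replace(spec), dt=dt)
    spec.vel_gain = _GAIN_CACHE[key]
    return spec


@dataclass
class Phase:
    """One environment visit within a protocol."""

    env: Environment
    duration: float
    learning: bool = True
    dynamic_cues: bool = False
    dark: bool = False  # no visual input and no visual feedback

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase dwell time must be positive")


@dataclass
class Protocol:
    """A full experiment: phases, trajectory source, variant, seeds."""

    name: str
    phases: list[Phase]
    dt: float = 0.005
    seed: int = 0
    model: str = "full"  # 'full' | 'direct'
    rule: str = "mosa"
    alb_only: bool = False  # sensor-level protocols skip the HD circuit
    feedback_on: bool = True
    noise_rel: float = 0.0  # uniform visual noise, fraction of channel 1-norm
    het_eta: bool = False  # near-zero Hebbian rate for half the dRSC cells
    test_speed: float = 60.0
    test_duration: float = 60.0
    test_each_phase: bool = True
    test_layers: tuple[str, ...] = ()  # e.g. ("hd", "drsc"): circuit tuning per phase
    trajectory: Trajectory | None = None
    mean_speed: float = 72.88  # deg/s, matches the reference recordings

    def __post_init__(self) -> None:
        if self.model not in ("full", "direct"):
            raise ValueError(f"unknown model variant {self.model!r}")
        if self.alb_only and self.model == "direct":
            raise ValueError("the direct variant has no aLB layer to run alone")
        for ph in self.phases:
            for cue in ph.env.cues:
                if cue.feature_id not in ph.env.feature_ids:
                    raise ValueError("phase environment references unknown feature")


class HDNetwork:
    """The assembled model: visual channels -> (aLB) -> RSC loop -> attractor."""

    def __init__(
        self,
        config: ModelConfig,
        feature_ids: tuple[str, ...],
        rng: np.random.Generator,
        model: str = "full",
        rule: str = "mosa",
        het_eta: bool = False,
        with_circuit: bool = True,
    ):
        self.config = config
        self.feature_ids = tuple(feature_ids)
        self.model = model
        self.with_circuit = with_circuit
        n_vis = config.n_vis
        self.alb: AlbLayer | None = None
        if model == "full":
            self.alb = AlbLayer(config.alb, self.feature_ids, n_vis, rng, rule=rule)
        if with_circuit:
            spec = _calibrated(replace(config.attractor), config.dt)
            self.attractor = Attractor(spec)
            n = spec.n
            rp = config.rsc
            n_in = config.alb.n if model == "full" else n_vis * len(self.feature_ids)
            eta_in = rp.eta_in2d
            eta_g = rp.eta_g2d
            if het_eta:
                # half the dRSC population learns at near-zero rate
                mask = np.ones(n)
                mask[rng.permutation(n)[: n // 2]] = 1e-3
                eta_in = rp.eta_in2d * mask
                eta_g = rp.eta_g2d * mask
            prefs = np.deg2rad(spec.preferred)
            bias = rp.init_bias * np.exp(
                rp.init_bias_kappa * (np.cos(prefs[:, None] - prefs[None, :]) - 1.0)
            )
            weights = RscWeights(
                W_in2d=rng.uniform(0.0, rp.init_scale_in2d, size=(n, n_in)),
                W_g2d=rng.uniform(0.0, rp.init_scale_g2d, size=(n, n)) + bias,
                w_max=rp.w_max,
                w_max_g=rp.w_max_g2d,
                eta_in2d=eta_in,
                eta_g2d=eta_g,
                norm_mode=rp.norm_mode,
            )
            self.rsc = RscLoop(
                n,
                weights,
                tau=rp.tau,
                transfer_g=rp.transfer_g,
                transfer_d=rp.transfer_d,
                g_hd2g=rp.g_hd2g,
                g_gi_g=rp.g_gi_g,
                g_gi_d=rp.g_gi_d,
                g_g2d=rp.g_g2d,
                g_in2d=rp.g_in2d,
            )
            # each dRSC cell feeds back onto the attractor cell matching its
            # initial preferred direction (cells are conventionally labelled
            # by that direction); realized as a fixed 0/1 assignment
            smooth = np.exp(
                spec.kappa
                * (np.cos(np.deg2rad(spec.preferred[:, None] - spec.preferred[None, :])) - 1.0)
            )
            self._fb_assign = np.argmax(weights.W_g2d @ smooth, axis=1)

    def input_rates(self, visual: dict[str, np.ndarray]) -> np.ndarray:
        """The dRSC landmark input: aLB rates (full) or stacked channels (direct)."""
        if self.model == "full":
            assert self.alb is not None
            return self.alb.f
        return np.concatenate([visual[fid] for fid in self.feature_ids])

    def feedback_vector(self) -> np.ndarray:
        """dRSC rates routed to their assigned attractor cells."""
        fb = np.zeros(self.attractor.spec.n)
        np.add.at(fb, self._fb_assign, self.rsc.f_d)
        return fb

    def step(
        self,
        visual: dict[str, np.ndarray],
        omega: float,
        dt: float,
        learning: bool,
        feedback_on: bool = True,
        dark: bool = False,
    ) -> None:
        self.last_alb_update = 0.0
        if self.alb is not None:
            if dark:
                self.alb.f[:] = 0.0
                self.alb.a[:] = 0.0
            else:
                self.alb.step(visual, dt)
                if learning:
                    self.last_alb_update = self.alb.learn(visual)
        if not self.with_circuit:
            return
        f_in = (
            np.zeros_like(self.rsc.weights.W_in2d[0])
            if dark
            else self.input_rates(visual)
        )
        fb = self.feedback_vector() if (feedback_on and not dark) else None
        self.attractor.step(omega, dt, feedback=fb)
        self.rsc.step(self.attractor.f, f_in, dt)
        if learning:
            self.rsc.learn(f_in)

    def activity_snapshot(self) -> dict:
        """Copy of all layer activations/rates (weights excluded)."""
        out = {}
        if self.alb is not None:
            out["alb"] = (self.alb.a.copy(), self.alb.f.copy())
        if self.with_circuit:
            out["attr"] = (self.attractor.a.copy(), self.attractor.f.copy())
            out["rsc"] = (
                self.rsc.a_g.copy(),
                self.rsc.f_g.copy(),
                self.rsc.a_d.copy(),
                self.rsc.f_d.copy(),
            )
        return out

    def restore_activity(self, snap: dict) -> None:
        if self.alb is not None:
            self.alb.a[:], self.alb.f[:] = snap["alb"]
        if self.with_circuit:
            self.attractor.a[:], self.attractor.f[:] = snap["attr"]
            self.rsc.a_g[:], self.rsc.f_g[:], self.rsc.a_d[:], self.rsc.f_d[:] = snap["rsc"]

    def reset_activity(self, hd: float | None = None) -> None:
        if self.alb is not None:
            self.alb.reset_state()
        if self.with_circuit:
            self.rsc.reset_state()
            if hd is not None:
                self.attractor.seed_bump(hd)

    def weight_checksum(self) -> str:
        h = hashlib.sha256()
        if self.alb is not None:
            for fid in self.feature_ids:
                h.update(np.ascontiguousarray(self.alb.weights[fid]))
        if self.with_circuit:
            h.update(np.ascontiguousarray(self.rsc.weights.W_in2d))
            h.update(np.ascontiguousarray(self.rsc.weights.W_g2d))
        return h.hexdigest()


@dataclass
class RunResult:
    """Artifacts of one protocol run."""

    protocol: Protocol
    recruited_intermediate: list[set[int]]
    recruited_final: list[set[int]]
    reps_final: list[RepresentationMap]
    alb_snapshots: list[dict[str, np.ndarray]]
    update_magnitude: np.ndarray  # mean |dW| of the aLB rule per logged step
    decode_log: np.ndarray  # columns: time, true hd, decoded hd (circuit runs)
    network: HDNetwork
    reps_circuit: list[dict[str, RepresentationMap]] = field(default_factory=list)
    test_envs: list[Environment] = field(default_factory=list)
    test_start_hds: list[float] = field(default_factory=list)

    def summary(self) -> dict:
        from .analysis import heading_error, iou

        out: dict = {
            "name": self.protocol.name,
            "n_phases": len(self.protocol.phases),
            "recruited_final_counts": [len(s) for s in self.recruited_final],
        }
        n = len(self.recruited_final)
        if n:
            out["iou_diag_final"] = [
                iou(self.recruited_final[i], self.recruited_final[i]) for i in range(n)
            ]
        if self.recruited_intermediate:
            out["iou_intermediate_vs_final"] = [
                iou(a, b)
                for a, b in zip(self.recruited_intermediate, self.recruited_final)
            ]
        if self.decode_log.size:
            mean, sem = heading_error(self.decode_log[:, 2], self.decode_log[:, 1])
            out["heading_error_mean"] = mean
            out["heading_error_sem"] = sem
        return out


def _static_env(env: Environment) -> Environment:
    """The environment with all cue dynamics frozen at their current state."""
    return replace(
        env, cues=tuple(replace(c, dynamics=CueDynamics()) for c in env.cues)
    )


def test_recruitment(
    net: HDNetwork,
    env: Environment,
    start_hd: float,
    protocol: Protocol,
    epsilon: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[set[int], np.ndarray, np.ndarray]:
    """Frozen-weights aLB test: rotate uniformly, log rates, report recruits.

    Recruitment uses the binned-tuning definition (peak of the mean rate per
    true-HD bin), which averages over the repeated sweeps of each direction.
    """
    assert net.alb is not None
    traj = test_rotation(start_hd, protocol.test_speed, protocol.test_duration, protocol.dt)
    feats = net.feature_ids
    net.alb.reset_state()
    log = np.empty((len(traj), net.alb.params.n))
    env = _static_env(env)
    for k in range(len(traj)):
        vis = channel_response(
            env, traj.hd[k], feature_ids=feats, rng=rng, noise_rel=protocol.noise_rel
        )
        log[k] = net.alb.step(vis, protocol.dt)
    rep = build_representation(log, traj.hd, epsilon=epsilon)
    return rep.recruited, log, traj.hd


def test_circuit(
    net: HDNetwork,
    env: Environment,
    start_hd: float,
    protocol: Protocol,
    layers: tuple[str, ...] = ("hd",),
    rng: np.random.Generator | None = None,
) -> dict[str, RepresentationMap]:
    """Frozen-weights full-loop test; returns tuning maps per requested layer."""
    traj = test_rotation(start_hd, protocol.test_speed, protocol.test_duration, protocol.dt)
    feats = net.feature_ids
    net.reset_activity(hd=start_hd)
    env = _static_env(env)
    logs = {name: np.empty((len(traj), net.attractor.spec.n)) for name in layers}
    for k in range(len(traj)):
        vis = channel_response(
            env, traj.hd[k], feature_ids=feats, rng=rng, noise_rel=protocol.noise_rel
        )
        net.step(vis, traj.omega[k], protocol.dt, learning=False, feedback_on=protocol.feedback_on)
        if "hd" in logs:
            logs["hd"][k] = net.attractor.f
        if "grsc" in logs:
            logs["grsc"][k] = net.rsc.f_g
        if "drsc" in logs:
            logs["drsc"][k] = net.rsc.f_d
    return {name: build_representation(log, traj.hd) for name, log in logs.items()}


def run_protocol(p: Protocol, config: ModelConfig | None = None) -> RunResult:
    """Execute a protocol: per-phase learning, per-phase and final testing.

    All randomness derives from p.seed.  During testing phases every learning
    rate is zero and the weight state is bit-identical before and after.
    """
    cfg = config or default_config()
    rng = np.random.default_rng(p.seed)
    feats: list[str] = []
    for ph in p.phases:
        for fid in ph.env.feature_ids:
            if fid not in feats:
                feats.append(fid)
    feats_t = tuple(feats)

    net = HDNetwork(
        cfg,
        feats_t,
        rng,
        model=p.model,
        rule=p.rule,
        het_eta=p.het_eta,
        with_circuit=not p.alb_only,
    )

    total = sum(ph.duration for ph in p.phases)
    traj = p.trajectory or synth_trajectory(
        total, target_mean_speed=p.mean_speed, dt=p.dt, seed=p.seed + 1
    )
    if traj.duration + 1e-9 < total:
        raise ValueError("trajectory shorter than the protocol's total dwell time")

    if not p.alb_only:
        net.attractor.seed_bump(traj.hd[0])

    idx = 0
    t = 0.0
    decim = max(1, int(round(0.05 / p.dt)))  # decode log every 50 ms
    decode_rows: list[tuple[float, float, float]] = []
    update_mag: list[float] = []
    snapshots: list[dict[str, np.ndarray]] = []
    inter_sets: list[set[int]] = []
    reps_circuit: list[dict[str, RepresentationMap]] = []
    test_envs: list[Environment] = []
    test_hds: list[float] = []

    per_second = int(round(1.0 / p.dt))
    accum = 0.0
    step_count = 0
    prev_phase_env = None
    env = None
    for ph in p.phases:
        # a phase sharing the previous phase's Environment object continues
        # from the advanced cue state (mid-protocol snapshots of one ongoing
        # unstable scenery); a new object resets to its declared state
        env = env if (ph.env is prev_phase_env and env is not None) else ph.env
        prev_phase_env = ph.env
        n_steps = int(round(ph.duration / p.dt))
        for k in range(n_steps):
            hd, om = float(traj.hd[idx]), float(traj.omega[idx])
            idx += 1
            if ph.dynamic_cues:
                env = advance_cues(env, t, p.dt, rng)
            vis = (
                {}
                if ph.dark
                else channel_response(
                    env, hd, t=t, rng=rng, feature_ids=feats_t, noise_rel=p.noise_rel
                )
            )
            net.step(
                vis,
                om,
                p.dt,
                learning=ph.learning,
                feedback_on=p.feedback_on,
                dark=ph.dark,
            )
            accum += net.last_alb_update
            step_count += 1
            if step_count % per_second == 0:
                update_mag.append(accum / per_second)
                accum = 0.0
            if not p.alb_only and k % decim == 0:
                try:
                    decoded = net.attractor.decode()
                except Exception:
                    decoded = np.nan
                decode_rows.append((t, hd, decoded))
            t += p.dt
        end_hd = float(traj.hd[idx - 1])
        test_env = _static_env(env)
        test_envs.append(test_env)
        test_hds.append(end_hd)
        if net.alb is not None:
            snapshots.append(net.alb.snapshot())
        if p.test_each_phase and net.alb is not None:
            act = net.activity_snapshot()
            rec, _, _ = test_recruitment(net, test_env, end_hd, p, rng=rng)
            inter_sets.append(rec)
            net.restore_activity(act)
        if p.test_layers and not p.alb_only:
            act = net.activity_snapshot()
            reps_circuit.append(
                test_circuit(net, test_env, end_hd, p, layers=p.test_layers, rng=rng)
            )
            net.restore_activity(act)

    final_sets: list[set[int]] = []
    reps_final: list[RepresentationMap] = []
    if net.alb is not None:
        for env_i, hd_i in zip(test_envs, test_hds):
            rec, log, hd_log = test_recruitment(net, env_i, hd_i, p, rng=rng)
            final_sets.append(rec)
            reps_final.append(build_representation(log, hd_log))
            net.alb.reset_state()

    return RunResult(
        protocol=p,
        recruited_intermediate=inter_sets,
        recruited_final=final_sets,
        reps_final=reps_final,
        alb_snapshots=snapshots,
        update_magnitude=np.asarray(update_mag),
        decode_log=np.asarray(decode_rows) if decode_rows else np.empty((0, 3)),
        network=net,
        reps_circuit=reps_circuit,
        test_envs=test_envs,
        test_start_hds=test_hds,
    )


# ---------------------------------------------------------------------------
# scenario library

_N = 90.0  # allocentric North in degrees (East = 0, anticlockwise positive)
_E, _W, _S = 0.0, -180.0, -90.0


def _fig2_cues(rotation: float = 0.0) -> tuple[Cue, ...]:
    """Bimodal narrow 'red' cues North/South plus a broad 'blue' cue East."""
    return (
        Cue("red", "bimodal", (wrap_deg(_N + rotation), wrap_deg(_S + rotation)), kappa=20.0),
        Cue("blue", "broad", (wrap_deg(_E + rotation),), kappa=20.0, width=90.0),
    )


def _capacity_env(k: int, n_vis: int, green_kappa: float = 20.0) -> Environment:
    """Shared narrow red + broad blue; green shifted 36 deg ACW per environment."""
    cues = (
        Cue("red", "unimodal", (_N,), kappa=20.0),
        Cue("blue", "broad", (_E,), kappa=20.0, width=90.0),
        Cue("green", "unimodal", (wrap_deg(_W + 36.0 * k),), kappa=green_kappa),
    )
    return Environment(f"env{k + 1}", cues, ("red", "blue", "green"), n_per_channel=n_vis)


def scenario_library(
    name: str,
    seed: int = 0,
    dt: float = 0.005,
    n_vis: int = 360,
    duration_scale: float = 1.0,
    n_envs: int | None = None,
    **kwargs,
) -> Protocol:
    """Fully parameterized protocols for every study scenario.

    duration_scale shrinks every dwell time proportionally so each scenario
    has a fast-running miniature twin; layer sizes and gains are unchanged so
    the dynamical regime is preserved.
    """
    feats = ("red", "blue", "green")
    scale = duration_scale

    def env_of(cues, nm="env"):
        return Environment(nm, cues, feats, n_per_channel=n_vis)

    if name == "fig2":
        p = [Phase(env_of(_fig2_cues()), 1200.0 * scale)]
        return Protocol(name, p, dt=dt, seed=seed, alb_only=True, **kwargs)

    if name == "fig3a_moving":
        moving = (
            Cue("red", "bimodal", (_N, _S), kappa=20.0),
            Cue("blue", "broad", (_E,), kappa=20.0, width=90.0, dynamics=CueDynamics("rotate", speed=90.0)),
        )
        p = [Phase(env_of(moving), 1200.0 * scale, dynamic_cues=True)]
        return Protocol(name, p, dt=dt, seed=seed, alb_only=True, **kwargs)

    if name == "fig3b_teleport":
        tele = (
            Cue("red", "bimodal", (_N, _S), kappa=20.0),
            Cue("blue", "broad", (_E,), kappa=20.0, width=90.0, dynamics=CueDynamics("teleport", period=10.0)),
        )
        p = [Phase(env_of(tele), 1200.0 * scale, dynamic_cues=True)]
        return Protocol(name, p, dt=dt, seed=seed, alb_only=True, **kwargs)

    if name == "fig3c_novel":
        rb = env_of(_fig2_cues(), "red-blue")
        rbg = env_of(
            _fig2_cues() + (Cue("green", "unimodal", (_W,), kappa=25.0),), "red-blue-green"
        )
        p = [
            Phase(rb, 400.0 * scale),
            Phase(rbg, 400.0 * scale),
            Phase(rb, 400.0 * scale),
        ]
        return Protocol(name, p, dt=dt, seed=seed, alb_only=True, **kwargs)

    if name in ("fig4_capacity", "s10_noise"):
        n_env = n_envs or 10
        noise = 0.05 if name == "s10_noise" else kwargs.pop("noise_rel", 0.0)
        p = [Phase(_capacity_env(k, n_vis), 120.0 * scale) for k in range(n_env)]
        return Protocol(
            name, p, dt=dt, seed=seed, alb_only=True, noise_rel=noise, **kwargs
        )

    if name == "fig5_mirrored":
        dwell = 60.0 * scale
        total = 1200.0 * scale
        env1 = env_of(_fig2_cues() + (Cue("green", "unimodal", (_W,), kappa=25.0),), "envI")
        env2 = env_of(
            tuple(
                replace(c, centers=tuple(float(wrap_deg(x + 180.0)) for x in c.centers))
                for c in env1.cues
            ),
            "envII",
        )
        n_alt = max(2, int(round(total / dwell)))
        p = [Phase(env1 if k % 2 == 0 else env2, dwell) for k in range(n_alt)]
        return Protocol(name, p, dt=dt, seed=seed, test_each_phase=False, **kwargs)

    if name == "fig5_mirrored_odor":
        # mirrored pair with a distinct, direction-independent odor cue per
        # compartment (odors rendered as constant 'visual' channels)
        dwell = 60.0 * scale
        total = 1200.0 * scale
        ofeats = feats + ("odor_blue", "odor_purple")
        cues1 = _fig2_cues() + (
            Cue("green", "unimodal", (_W,), kappa=25.0),
            Cue("odor_blue", "constant", (0.0,)),
        )
        env1 = Environment("envI", cues1, ofeats, n_per_channel=n_vis)
        cues2 = tuple(
            replace(c, centers=tuple(float(wrap_deg(x + 180.0)) for x in c.centers))
            for c in cues1[:-1]
        ) + (Cue("odor_purple", "constant", (0.0,)),)
        env2 = Environment("envII", cues2, ofeats, n_per_channel=n_vis)
        n_alt = max(2, int(round(total / dwell)))
        p = [Phase(env1 if k % 2 == 0 else env2, dwell) for k in range(n_alt)]
        return Protocol(name, p, dt=dt, seed=seed, test_each_phase=False, **kwargs)

    if name == "fig7_rotation":
        p = [
            Phase(env_of(_fig2_cues(), "envI"), 600.0 * scale),
            Phase(env_of(_fig2_cues(rotation=120.0), "envII"), 600.0 * scale),
        ]
        return Protocol(name, p, dt=dt, seed=seed, test_each_phase=False, **kwargs)

    if name == "fig8_multienv":
        n_env = n_envs or 10
        p = [Phase(_capacity_env(k, n_vis), 120.0 * scale) for k in range(n_env)]
        return Protocol(name, p, dt=dt, seed=seed, test_each_phase=False, **kwargs)

    if name == "s9_capacity20":
        n_env = n_envs or 20
        rng = np.random.default_rng(seed)
        all_feats = ("c1", "c2", "c3", "c4", "c5", "c6")
        phases = []
        for k in range(n_env):
            chosen = rng.choice(6, size=3, replace=False)
            cues = tuple(
                Cue(all_feats[j], "unimodal", (float(rng.uniform(-180.0, 180.0)),), kappa=20.0)
                for j in chosen
            )
            phases.append(
                Phase(
                    Environment(f"env{k + 1}", cues, all_feats, n_per_channel=n_vis),
                    120.0 * scale,
                )
            )
        return Protocol(name, phases, dt=dt, seed=seed, alb_only=True, **kwargs)

    if name == "darkness":
        dark_env = Environment("dark", (), feats, n_per_channel=n_vis)
        p = [Phase(dark_env, 1200.0 * scale, learning=False, dark=True)]
        return Protocol(name, p, dt=dt, seed=seed, test_each_phase=False, **kwargs)

    raise ValueError(f"unknown scenario {name!r}; known: {list_scenarios()}")


def list_scenarios() -> list[str]:
    return [
        "fig2",
        "fig3a_moving",
        "fig3b_teleport",
        "fig3c_novel",
        "fig4_capacity",
        "fig5_mirrored",
        "fig5_mirrored_odor",
        "fig7_rotation",
        "fig8_multienv",
        "s9_capacity20",
        "s10_noise",
        "darkness",
    ]


def assemble_direct_model(protocol: Protocol) -> Protocol:
    """The same protocol with the aLB layer replaced by direct visual->dRSC
    Hebbian connections (all other components unchanged)."""
    return replace(protocol, model="direct", alb_only=False)
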