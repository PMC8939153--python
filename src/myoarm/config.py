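"""Run configuration: defaults, TOML loading/validation, serialization.

The configuration file is plain TOML.  Angles are expressed in **degrees**
at this surface (``*_deg`` keys) and converted to radians internally; all
other quantities are SI.  Every key is optional — an empty file yields the
full default configuration, including the standard task constants (1/150 s
step, 90° start, +45° target, ±2° and 0.001°/s success tolerances, 5 s
limit).

Tendon slack lengths default to ``"auto"``: they are solved at load time so
that, at the task's start angle, each muscle rests in isometric equilibrium
with activation at its floor and the two passive muscle torques cancel
exactly.  The weaker side (by ``f_max * a_min * moment arm``) rests at its
optimal CE length; the stronger side rests on the ascending force--length
limb at the CE length that balances the torques, which also makes the start
posture statically stable.
"""

from __future__ import annotations

import logging
import math
import tomllib
from dataclasses import dataclass, field

from .control import EmgChainParams
from .dynamics import ArmParams, SimConfig
from .errors import ConfigurationError, InputValidationError
from .geometry import ActuationConfig, PathGeometry, moment_arm, muscle_tendon_length
from .muscle import MuscleParams, init_muscle_state
from .task import TaskParams

__all__ = ["RunConfig", "default_config", "load_config", "loads_config", "dump_config",
           "calibrate_slack_lengths"]

log = logging.getLogger("myoarm")

DEG = math.pi / 180.0


@dataclass(frozen=True)
class RunConfig:
    """Fully validated bundle of all simulation parameters."""

    arm: ArmParams = field(default_factory=ArmParams)
    flexor: MuscleParams = field(default_factory=MuscleParams)
    extensor: MuscleParams = field(default_factory=MuscleParams)
    flexor_path: PathGeometry = field(default_factory=lambda: PathGeometry(0.28, 0.030, "flexor"))
    extensor_path: PathGeometry = field(
        default_factory=lambda: PathGeometry(0.28, 0.025, "extensor")
    )
    actuation: ActuationConfig = field(default_factory=ActuationConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    task: TaskParams = field(default_factory=TaskParams)
    emg: EmgChainParams = field(default_factory=EmgChainParams)
    seed: int = 0

    def __post_init__(self) -> None:
        theta0 = self.task.theta_start * DEG
        theta1 = self.task.theta_target * DEG
        for name, th in (("theta_start", theta0), ("theta_start+delta_target", theta1)):
            if not (self.arm.rom_min <= th <= self.arm.rom_max):
                raise ConfigurationError(
                    f"task.{name} = {th / DEG:.1f} deg lies outside the arm's range of motion"
                )
        if self.actuation.mode == "muscle":
            # fails loudly at load time if the rest equilibrium is unsolvable
            for p, g, side in (
                (self.flexor, self.flexor_path, "flexor"),
                (self.extensor, self.extensor_path, "extensor"),
            ):
                try:
                    init_muscle_state(theta0, p.a_min, g, p)
                except ConfigurationError as exc:
                    raise ConfigurationError(f"muscle.{side}: {exc}") from exc


def calibrate_slack_lengths(
    flexor: MuscleParams,
    extensor: MuscleParams,
    flexor_path: PathGeometry,
    extensor_path: PathGeometry,
    theta0: float,
) -> tuple[float, float]:
    """Solve tendon slack lengths for a balanced rest posture at ``theta0`` (rad).

    Returns ``(l_slack_flexor, l_slack_extensor)`` such that with activation
    at each muscle's floor the two muscles are in isometric equilibrium and
    their joint torques cancel.  The passively stronger side is placed on
    the ascending force--length limb so that flexing (shortening) it reduces
    its force — a statically stable rest posture.
    """
    r_f = moment_arm(theta0, flexor_path)
    r_e = moment_arm(theta0, extensor_path)
    cap_f = flexor.f_max * flexor.a_min * r_f
    cap_e = extensor.f_max * extensor.a_min * r_e

    def solve(p: MuscleParams, path: PathGeometry, fl: float) -> float:
        # CE length realizing force-length factor fl on the ascending limb
        x = 1.0 - p.w * math.sqrt(max(-math.log(fl), 0.0))
        l_ce = x * p.l_ce_opt
        if l_ce <= 0:
            raise ConfigurationError("slack calibration drove the CE length non-positive")
        force = p.f_max * p.a_min * fl
        strain = math.log(force / (p.f_max * p.c1) + 1.0) / p.c2
        l_mt = muscle_tendon_length(theta0, path)
        l_slack = (l_mt - l_ce) / (1.0 + strain)
        if l_slack <= 0:
            raise ConfigurationError(
                "slack calibration failed: tendon would need non-positive slack length"
            )
        return l_slack

    if cap_f >= cap_e:
        fl_f, fl_e = cap_e / cap_f, 1.0
    else:
        fl_f, fl_e = 1.0, cap_f / cap_e
    return solve(flexor, flexor_path, fl_f), solve(extensor, extensor_path, fl_e)


def default_config(**overrides) -> RunConfig:
    """The all-defaults configuration with auto-calibrated slack lengths."""
    return loads_config("", **overrides)


# --- TOML schema ----------------------------------------------------------

_ANGLE = DEG  # degree -> radian conversion marker

_SCHEMA = {
    "arm": {
        "inertia": None, "damping_b": None, "lig_k": None, "lig_c": None,
        "upper_len": None, "fore_len": None,
        "rom_min_deg": ("rom_min", _ANGLE), "rom_max_deg": ("rom_max", _ANGLE),
    },
    "sim": {"dt": None, "t_limit": None},
    "task": {
        "theta_start_deg": ("theta_start", 1.0), "delta_target_deg": ("delta_target", 1.0),
        "tol_theta_deg": ("tol_theta", 1.0), "tol_omega_deg_s": ("tol_omega", 1.0),
        "t_limit": None,
    },
    "actuation": {"mode": None, "t_max": None, "f_gen_max": None},
    "emg": {"fs_raw": None, "f_env": None, "gain": None, "adc_bits": None, "v_ref": None,
            "noise_seed": None},
}
_MUSCLE_KEYS = ("f_max", "l_ce_opt", "w", "v_max", "a_f", "fv_ecc_max", "l_slack",
                "c1", "c2", "tau_act", "tau_deact", "a_min")
_GEOM_KEYS = ("d_origin", "d_insert")


def _build_section(cls, section: str, raw: dict, schema: dict):
    kwargs = {}
    for key, value in raw.items():
        if key not in schema:
            log.warning("config: unknown key %s.%s ignored", section, key)
            continue
        entry = schema[key]
        if entry is None:
            kwargs[key] = value
        else:
            target, scale = entry
            kwargs[target] = value * scale if scale != 1.0 else value
    try:
        return cls(**kwargs)
    except InputValidationError as exc:
        raise ConfigurationError(f"config section [{section}]: {exc}") from exc


def loads_config(text: str, **overrides) -> RunConfig:
    """Parse a TOML string into a validated :class:`RunConfig`."""
    try:
        raw = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"config parse failure: {exc}") from exc
    raw.update(overrides)

    arm = _build_section(ArmParams, "arm", raw.pop("arm", {}), _SCHEMA["arm"])
    sim = _build_section(SimConfig, "sim", raw.pop("sim", {}), _SCHEMA["sim"])
    task = _build_section(TaskParams, "task", raw.pop("task", {}), _SCHEMA["task"])
    actuation = _build_section(
        ActuationConfig, "actuation", raw.pop("actuation", {}), _SCHEMA["actuation"]
    )
    emg = _build_section(EmgChainParams, "emg", raw.pop("emg", {}), _SCHEMA["emg"])

    geo_raw = raw.pop("geometry", {})
    paths = {}
    for side, d_o, d_i in (("flexor", 0.28, 0.030), ("extensor", 0.28, 0.025)):
        sec = geo_raw.pop(side, {})
        kwargs = {"d_origin": d_o, "d_insert": d_i}
        for key, value in sec.items():
            if key not in _GEOM_KEYS:
                log.warning("config: unknown key geometry.%s.%s ignored", side, key)
                continue
            kwargs[key] = value
        try:
            paths[side] = PathGeometry(side=side, **kwargs)
        except InputValidationError as exc:
            raise ConfigurationError(f"config section [geometry.{side}]: {exc}") from exc
    for key in geo_raw:
        log.warning("config: unknown key geometry.%s ignored", key)

    mus_raw = raw.pop("muscle", {})
    muscles = {}
    slack_auto = {}
    base = {
        "flexor": {"f_max": 1000.0},
        "extensor": {"f_max": 800.0},
    }
    for side in ("flexor", "extensor"):
        sec = mus_raw.pop(side, {})
        kwargs = dict(base[side])
        slack_auto[side] = True
        for key, value in sec.items():
            if key not in _MUSCLE_KEYS:
                log.warning("config: unknown key muscle.%s.%s ignored", side, key)
                continue
            if key == "l_slack":
                if value == "auto":
                    continue
                slack_auto[side] = False
            kwargs[key] = value
        try:
            muscles[side] = MuscleParams(**kwargs)
        except InputValidationError as exc:
            raise ConfigurationError(f"config section [muscle.{side}]: {exc}") from exc
    for key in mus_raw:
        log.warning("config: unknown key muscle.%s ignored", key)

    seed = raw.pop("seed", 0)
    for key in raw:
        log.warning("config: unknown top-level key %s ignored", key)

    if slack_auto["flexor"] or slack_auto["extensor"]:
        ls_f, ls_e = calibrate_slack_lengths(
            muscles["flexor"], muscles["extensor"], paths["flexor"], paths["extensor"],
            task.theta_start * DEG,
        )
        if slack_auto["flexor"]:
            muscles["flexor"] = muscles["flexor"].with_slack(ls_f)
        if slack_auto["extensor"]:
            muscles["extensor"] = muscles["extensor"].with_slack(ls_e)

    return RunConfig(
        arm=arm,
        flexor=muscles["flexor"],
        extensor=muscles["extensor"],
        flexor_path=paths["flexor"],
        extensor_path=paths["extensor"],
        actuation=actuation,
        sim=sim,
        task=task,
        emg=emg,
        seed=int(seed),
    )


def load_config(path) -> RunConfig:
    """Load and validate a TOML configuration file (missing keys default)."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, int):
        return str(value)
    return repr(float(value))


def dump_config(cfg: RunConfig) -> str:
    """Serialize a config to TOML text that round-trips through the loader."""
    a, t = cfg.arm, cfg.task
    lines = [f"seed = {cfg.seed}", ""]
    lines += ["[sim]", f"dt = {_fmt(cfg.sim.dt)}", f"t_limit = {_fmt(cfg.sim.t_limit)}", ""]
    lines += [
        "[arm]",
        f"inertia = {_fmt(a.inertia)}",
        f"damping_b = {_fmt(a.damping_b)}",
        f"rom_min_deg = {_fmt(a.rom_min / DEG)}",
        f"rom_max_deg = {_fmt(a.rom_max / DEG)}",
        f"lig_k = {_fmt(a.lig_k)}",
        f"lig_c = {_fmt(a.lig_c)}",
        f"upper_len = {_fmt(a.upper_len)}",
        f"fore_len = {_fmt(a.fore_len)}",
        "",
        "[task]",
        f"theta_start_deg = {_fmt(t.theta_start)}",
        f"delta_target_deg = {_fmt(t.delta_target)}",
        f"tol_theta_deg = {_fmt(t.tol_theta)}",
        f"tol_omega_deg_s = {_fmt(t.tol_omega)}",
        f"t_limit = {_fmt(t.t_limit)}",
        "",
        "[actuation]",
        f'mode = "{cfg.actuation.mode}"',
        f"t_max = {_fmt(cfg.actuation.t_max)}",
        f"f_gen_max = {_fmt(cfg.actuation.f_gen_max)}",
        "",
    ]
    for side, path in (("flexor", cfg.flexor_path), ("extensor", cfg.extensor_path)):
        lines += [
            f"[geometry.{side}]",
            f"d_origin = {_fmt(path.d_origin)}",
            f"d_insert = {_fmt(path.d_insert)}",
            "",
        ]
    for side, p in (("flexor", cfg.flexor), ("extensor", cfg.extensor)):
        lines.append(f"[muscle.{side}]")
        for key in _MUSCLE_KEYS:
            lines.append(f"{key} = {_fmt(getattr(p, key))}")
        lines.append("")
    e = cfg.emg
    lines += [
        "[emg]",
        f"fs_raw = {_fmt(e.fs_raw)}",
        f"f_env = {_fmt(e.f_env)}",
        f"gain = {_fmt(e.gain)}",
        f"adc_bits = {e.adc_bits}",
        f"v_ref = {_fmt(e.v_ref)}",
        f"noise_seed = {e.noise_seed}",
        "",
    ]
    return "\n".join(lines)
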