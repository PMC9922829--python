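"""Built-in parameter/IC presets and seeded synthetic inputs.

Every study condition of the model — the multistable censuses, the
bursting regimes, the stability-analysis bias values and the control
experiment — is available as a named preset holding the exact parameters
and the prescribed initial conditions, so all stages run and test with no
external data.  :func:`random_ics` supplies seeded uniform IC samples, and
:func:`make_reference_fixtures` writes small text regression baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import ControlParams, ModelParams

__all__ = [
    "Preset",
    "PRESETS",
    "builtin_preset",
    "FixtureSpec",
    "random_ics",
    "make_reference_fixtures",
]

log = logging.getLogger("hopfield3")


@dataclass(frozen=True)
class Preset:
    """A named study condition: parameters plus prescribed ICs."""

    name: str
    params: ModelParams
    ics: tuple
    control: ControlParams | None = None
    expected_count: int | None = None  # attractors expected by the census
    description: str = ""


def _pm(sym: float) -> tuple:
    return (0.0, 0.0, sym), (0.0, 0.0, -sym)


def _ics_z(*zs: float) -> tuple:
    return tuple((0.0, 0.0, z) for z in zs)


def _ics_x(*xs: float) -> tuple:
    return tuple((x, 0.0, 0.0) for x in xs)


def _build_presets() -> dict[str, Preset]:
    presets = {}

    def add(name, expected=None, ics=(), control=None, description="", **params):
        presets[name] = Preset(
            name=name,
            params=ModelParams().updated(**params),
            ics=tuple(np.asarray(ic, dtype=float) for ic in ics),
            control=control,
            expected_count=expected,
            description=description,
        )

    # symmetric (i1 = 0) multistability censuses
    add("multistable8", 8, _ics_z(1.32, -1.32, 3.46, -3.46, 0.21, -0.21, 1.09, -1.09),
        beta2=1.182,
        description="eight coexisting chaotic and periodic attractors, beta2=1.182")
    add("multistable6_x", 6, _ics_x(1.44, -1.44, 0.5, -0.5, 1.0, -1.0),
        beta2=1.183,
        description="six coexisting attractors seeded on the x1 axis, beta2=1.183")
    add("multistable6", 6, _ics_z(0.21, -0.21, 1.05, -1.05, 0.5, -0.5),
        beta2=1.206,
        description="six coexisting periodic attractors, beta2=1.206")
    add("multistable6_high", 6, _ics_z(0.69, -0.69, 0.4, -0.4, 1.0, -1.0),
        beta2=1.636,
        description="six coexisting attractors, beta2=1.636")

    # asymmetric (i1 = 0.001) censuses
    add("asym5", 5, _ics_z(0.42, -0.42, 0.18, -0.18, 0.6),
        beta2=1.114, i1=0.001,
        description="five coexisting asymmetric attractors, beta2=1.114, i1=0.001")
    add("asym6", 6, _ics_z(0.58, -0.58, 0.24, -0.24, 2.0, -2.0),
        beta2=1.173, i1=0.001,
        description="six coexisting asymmetric attractors, beta2=1.173, i1=0.001")
    add("asym7", 7, _ics_z(0.21, -0.21, 0.55, -0.55, -1.5, 0.7, 2.0),
        beta2=1.175, i1=0.001,
        description="seven coexisting asymmetric attractors, beta2=1.175, i1=0.001")

    # bursting regimes (modified synaptic weights)
    add("burst_periodic_sym", None, _ics_z(1.0, -1.0),
        beta2=1.41, w23=1.0,
        description="coexisting symmetric periodic bursting, beta2=1.41, w23=1")
    add("burst_periodic", None, _ics_z(1.0),
        beta2=1.78, w11=2.0,
        description="periodic bursting, beta2=1.78, w11=2")
    add("burst_chaotic", None, _ics_z(1.0, -1.0),
        beta2=1.05, w11=2.33,
        description="coexisting symmetric chaotic bursting, beta2=1.05, w11=2.33")

    # linear-augmentation control experiment on the 8-attractor state
    add("control", 8, _ics_z(1.32, -1.32, 3.46, -3.46, 0.21, -0.21, 1.09, -1.09),
        beta2=1.182, control=ControlParams(phi=0.0, eps=0.5, gamma=8.0),
        description="linear-augmentation control of the 8-attractor census, "
                    "eps=0.5, gamma=8, phi swept over [0, 0.29]")

    # bias values of the stability analysis (beta2 = 1.7)
    for i1 in (0.0, 0.4, 0.8):
        tag = f"bias{i1:g}".replace(".", "")
        add(tag, None, _ics_z(1.0), i1=i1,
            description=f"stability-analysis condition, beta2=1.7 (default), i1={i1:g}")

    return presets


#: Registry of named study conditions.
PRESETS: dict[str, Preset] = _build_presets()


def builtin_preset(name: str) -> Preset:
    """Look up a preset; an unknown name raises with the full registry listed."""
    try:
        return PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; available: {known}") from None


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded synthetic-input description (identical seed, identical output)."""

    seed: int = 0
    n_random_ics: int = 20
    ic_box: tuple = ((-2.0, 2.0), (-2.0, 2.0), (-2.0, 2.0))


def random_ics(spec: FixtureSpec) -> np.ndarray:
    """Uniform IC samples in ``spec.ic_box``, reproducible from the seed."""
    box = np.asarray(spec.ic_box, dtype=float)
    if box.ndim != 2 or box.shape[1] != 2 or np.any(box[:, 1] <= box[:, 0]):
        raise ValueError(f"degenerate IC box: {spec.ic_box}")
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(box[:, 0], box[:, 1], size=(spec.n_random_ics, box.shape[0]))


def make_reference_fixtures(
    spec: FixtureSpec,
    outdir,
    t_end: float = 20.0,
    dt: float = 0.005,
    include_census: bool = False,
) -> dict[str, Path]:
    """Write plain-text regression baselines for every preset.

    For each preset the trajectory endpoint at ``t_end`` from its first IC
    is stored (tab-separated, commented header); with ``include_census``
    the census count is stored too.  Regeneration with unchanged inputs is
    bit-stable for fixed dt; cross-platform agreement is expected to 1e-8.
    """
    from . import __version__
    from .integrate import integrate_fixed
    from .multistability import census

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, preset in sorted(PRESETS.items()):
        tr = integrate_fixed(preset.ics[0], preset.params, t_end, dt=dt)
        lines = [
            f"# hopfield3 {__version__} reference fixture: preset={name} "
            f"t_end={t_end} dt={dt} seed={spec.seed}",
            "\t".join(f"{v!r}" for v in tr.final_state()),
        ]
        if include_census:
            res = census(preset.params, preset.ics, control=preset.control)
            lines.append(f"# census_count\t{res.count}")
        path = outdir / f"{name}.tsv"
        path.write_text("\n".join(lines) + "\n")
        log.info("wrote fixture %s (dt=%g, t_end=%g, seed=%d)", path, dt, t_end, spec.seed)
        written[name] = path
    return written
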