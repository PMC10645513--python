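"""Named slip profiles, amplitude presets and the reference embryo geometry."""

from __future__ import annotations

import numpy as np

from .geometry import EmbryoGeometry, make_geometry
from .stokes import SlipProfile
from .transport import GaussianSum, drosophila_slip

__all__ = [
    "embryo_geometry",
    "slip_profile",
    "amplitude_preset",
    "list_slip_profiles",
    "list_amplitude_presets",
    "WILD_TYPE_CHI_UM",
    "MUTANT_CHI_UM",
]

# Printed experimental estimates of the total cortical forcing (um); taken
# as given inputs — the presets below are calibrated to realize them.
WILD_TYPE_CHI_UM = 129.0
MUTANT_CHI_UM = 57.0


def embryo_geometry() -> EmbryoGeometry:
    """The fly-embryo reference geometry, bx = 110 um, bz = 270 um."""
    return make_geometry(110.0, 270.0)


def _mode_shape(m: int, g: EmbryoGeometry):
    from .geometry import assoc_legendre_P1

    def shape(zeta):
        zeta = np.asarray(zeta, dtype=float)
        return g.tau0 / np.sqrt(g.tau0**2 - zeta**2) * assoc_legendre_P1(m, zeta)

    return shape


def slip_profile(name: str, g: EmbryoGeometry | None = None) -> SlipProfile:
    """Look up a named slip profile.

    ``"drosophila"`` — the shifted-sine embryo profile; ``"mode-m"`` for
    m = 1..4 — the pure m-th basis mode of the slip expansion (produces an
    m-vortex flow); ``"symmetric-sine"`` — the symmetrized profile of the
    reduced 1D model.
    """
    g = g or embryo_geometry()
    if name == "drosophila":
        return SlipProfile(shape=drosophila_slip, name=name)
    if name == "symmetric-sine":
        return SlipProfile(shape=lambda z: -np.sin(np.pi * np.asarray(z, dtype=float)), name=name)
    if name.startswith("mode-"):
        m = int(name.split("-", 1)[1])
        if not 1 <= m <= 8:
            raise KeyError(f"mode index out of range in {name!r}")
        import warnings

        with warnings.catch_warnings():
            # basis modes do not vanish at the poles; that is expected here
            warnings.simplefilter("ignore")
            return SlipProfile(shape=_mode_shape(m, g), name=name)
    raise KeyError(f"unknown slip profile {name!r}")


def list_slip_profiles() -> list[str]:
    return ["drosophila", "symmetric-sine"] + [f"mode-{m}" for m in range(1, 5)]


def _calibrated_sum(a, b, c, chi_target: float) -> GaussianSum:
    raw = np.sqrt(2.0 * np.pi) * float(np.dot(a, c))
    scale = chi_target / raw
    return GaussianSum(a=tuple(a), b=tuple(b), c=tuple(np.asarray(c) * scale))


def amplitude_preset(name: str) -> GaussianSum:
    """Synthetic cortical-amplitude presets.

    Gaussian-sum stand-ins for the contraction-peak time series of a
    wild-type-like and a flow-dampened mutant-like embryo.  Only the total
    chi each preset realizes (129 um and 57 um respectively) is calibrated
    to the published estimates; the peak positions and widths are synthetic.
    """
    if name == "wild-type-like":
        return _calibrated_sum(
            a=(0.15, 0.22, 0.30), b=(300.0, 800.0, 1300.0), c=(60.0, 70.0, 80.0),
            chi_target=WILD_TYPE_CHI_UM,
        )
    if name == "mutant-like":
        return _calibrated_sum(
            a=(0.10, 0.13), b=(400.0, 1000.0), c=(85.0, 90.0),
            chi_target=MUTANT_CHI_UM,
        )
    raise KeyError(f"unknown amplitude preset {name!r}")


def list_amplitude_presets() -> list[str]:
    return ["wild-type-like", "mutant-like"]
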