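"""Default migalastat parameter set and structured parameter-file I/O.

The defaults describe the apparent (oral) disposition of migalastat calibrated
to the printed noncompartmental summaries of the single-dose study: apparent
clearance ~16.3 L/h and terminal half-life ~4 h at normal renal function
(eGFR ~90), falling to ~2.2 L/h and ~16 h at an eGFR of 10, with Vz/F in the
50-100 L range.  The renal effect on CL/F is linear in eGFR up to
120 mL/min/1.73 m2 and constant above; total CL/F scales with the renal
factor (non-renal elimination falls proportionally with renal function, so
the renal *fraction* of elimination is handled separately by the study
generator).

Parameter files are YAML/JSON mappings using the field's customary symbols
(``CL/F``, ``V2/F``, ``Q/F``, ``V3/F``, ``Ka_intercept``, ``Ka_slope``,
``ALAG``, ``F1``, omega block, sigma block).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import FixedEffects, OmegaSpec, ResidualSpec

__all__ = [
    "default_fixed_effects",
    "default_omega",
    "default_residual",
    "load_parameters",
    "dump_parameters",
    "MIGALASTAT_MOLAR_MASS",
    "PLASMA_LLOQ",
]

#: migalastat free base C6H13NO4 (g/mol); used for the uM -> ng/mL conversion
MIGALASTAT_MOLAR_MASS = 163.17

#: plasma assay lower limit of quantification (ng/mL)
PLASMA_LLOQ = 5.88

_SYMBOLS = {
    "CL/F": "cl",
    "V2/F": "v2",
    "Q/F": "q",
    "V3/F": "v3",
    "Ka_intercept": "ka_intercept",
    "Ka_slope": "ka_slope",
    "ALAG": "alag",
    "F1": "f1",
    "eGFR_intercept": "egfr_intercept",
    "eGFR_slope": "egfr_slope",
    "eGFR_ref": "egfr_ref",
    "FD_CL": "fd_cl",
    "FD_V2": "fd_v2",
}


def default_fixed_effects() -> FixedEffects:
    """Typical values for a 70 kg non-Fabry subject at eGFR 90."""
    return FixedEffects(
        cl=16.3,          # L/h
        v2=20.0,          # L
        q=6.0,            # L/h
        v3=25.0,          # L
        ka_intercept=0.30,  # 1/h
        ka_slope=0.025,     # 1/h per h of TAD
        alag=0.7,           # h
        f1=1.0,
        egfr_intercept=0.026886,
        egfr_slope=0.010812,
        egfr_ref=90.0,
        fd_cl=0.85,
        fd_v2=1.10,
    )


def default_omega() -> OmegaSpec:
    """Log-normal IIV: ~30% CV on CL, ~25% on V2 (correlated), ~30% on Ka."""
    return OmegaSpec(
        var_eta_cl=0.09,
        var_eta_v2=0.0625,
        corr_cl_v2=0.4,
        var_eta_ka_slope=0.09,
        var_eta_ka_intercept=0.09,
    )


def default_residual() -> ResidualSpec:
    """Combined error: 20% proportional plus additive 0.5 x plasma LLOQ."""
    return ResidualSpec(proportional_sd=0.20, additive_sd=0.5 * PLASMA_LLOQ,
                        kind="combined")


def load_parameters(path: str | Path) -> tuple[FixedEffects, OmegaSpec, ResidualSpec]:
    """Read a YAML/JSON parameter file; missing entries fall back to defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} does not contain a mapping")

    theta_kwargs = {}
    theta_block = data.get("theta", data)
    for symbol, field_name in _SYMBOLS.items():
        if symbol in theta_block:
            theta_kwargs[field_name] = float(theta_block[symbol])
    defaults = default_fixed_effects()
    fixed = FixedEffects(**{**_as_dict(defaults), **theta_kwargs})

    om = data.get("omega", {})
    omega = OmegaSpec(
        var_eta_cl=float(om.get("var_CL", default_omega().var_eta_cl)),
        var_eta_v2=float(om.get("var_V2", default_omega().var_eta_v2)),
        corr_cl_v2=float(om.get("corr_CL_V2", default_omega().corr_cl_v2)),
        var_eta_ka_slope=float(om.get("var_Ka_slope", default_omega().var_eta_ka_slope)),
        var_eta_ka_intercept=float(
            om.get("var_Ka_intercept", default_omega().var_eta_ka_intercept)),
    )
    sg = data.get("sigma", {})
    residual = ResidualSpec(
        proportional_sd=float(sg.get("proportional", default_residual().proportional_sd)),
        additive_sd=float(sg.get("additive", default_residual().additive_sd)),
        kind=str(sg.get("kind", "combined")),
    )
    return fixed, omega, residual


def dump_parameters(fixed: FixedEffects, omega: OmegaSpec, residual: ResidualSpec,
                    path: str | Path) -> None:
    """Write a parameter file using the customary symbol names."""
    d = _as_dict(fixed)
    payload = {
        "theta": {symbol: d[field_name] for symbol, field_name in _SYMBOLS.items()},
        "omega": {
            "var_CL": omega.var_eta_cl,
            "var_V2": omega.var_eta_v2,
            "corr_CL_V2": omega.corr_cl_v2,
            "var_Ka_slope": omega.var_eta_ka_slope,
            "var_Ka_intercept": omega.var_eta_ka_intercept,
        },
        "sigma": {
            "proportional": residual.proportional_sd,
            "additive": residual.additive_sd,
            "kind": residual.kind,
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _as_dict(fixed: FixedEffects) -> dict:
    from dataclasses import asdict

    return asdict(fixed)
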