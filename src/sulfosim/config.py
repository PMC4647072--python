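"""Configuration files: TOML parameter/initial-state round-trip and fixtures.

A configuration has two flat sections, ``[parameters]`` (the
:class:`~sulfosim.model_core.ModelParameters` fields) and
``[initial_state]`` (the initial-condition table: ``la0``, ``tdw_ini``,
``dw_fl_ini``, ``ldw_bl_ini``, ``qs_tot_ini``, ``a_qs``, ``b_qs``,
``qs_bl_ini``, ``qs_rest_ini``).  Keys shared by both sections (``la0``,
``dw_fl_ini``, ``a_qs``, ``b_qs``) describe the same quantity; the
initial-state value wins when both are present.  Numbers are serialized
with ``repr`` (17 significant digits), so a load → save → load round-trip
is exact.

Four fixtures transcribing the published calibration/initialization tables
ship with the package: ``hs_exp1``, ``ls_exp1``, ``hs_exp2``, ``ls_exp2``
(high/low sulfur supply, calibration and evaluation experiments).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import tomllib
from importlib import resources
from pathlib import Path

from .model_core import ModelParameters, PlantState, initial_state_from

__all__ = [
    "SCHEMA_VERSION",
    "ConfigError",
    "load_config",
    "save_config",
    "fixture_path",
    "load_fixture",
    "FIXTURES",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

FIXTURES = ("hs_exp1", "ls_exp1", "hs_exp2", "ls_exp2")

INITIAL_STATE_KEYS = (
    "la0",
    "tdw_ini",
    "dw_fl_ini",
    "ldw_bl_ini",
    "qs_tot_ini",
    "a_qs",
    "b_qs",
    "qs_bl_ini",
    "qs_rest_ini",
)

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_STR_FIELDS = {"la_provider", "leaf_fall_provider"}


class ConfigError(ValueError):
    """Malformed or inconsistent configuration file."""


def load_config(path: str | Path) -> tuple[ModelParameters, PlantState]:
    """Load a TOML configuration into (parameters, initial state)."""
    path = Path(path)
    try:
        with path.open("rb") as fh:
            doc = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    if "parameters" not in doc or "initial_state" not in doc:
        raise ConfigError(
            f"{path}: configuration needs [parameters] and [initial_state] sections"
        )
    raw_params = dict(doc["parameters"])
    raw_init = dict(doc["initial_state"])

    unknown = set(raw_params) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown parameter keys {sorted(unknown)}")
    unknown = set(raw_init) - set(INITIAL_STATE_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown initial-state keys {sorted(unknown)}")
    missing = set(INITIAL_STATE_KEYS) - set(raw_init)
    if missing:
        raise ConfigError(f"{path}: missing initial-state keys {sorted(missing)}")

    # shared keys: the initial-state table is authoritative
    for key in ("la0", "dw_fl_ini", "a_qs", "b_qs"):
        raw_params[key] = raw_init[key]
    raw_params.setdefault("qs_ini", raw_init["qs_tot_ini"])

    for key, value in raw_params.items():
        if key in _STR_FIELDS:
            if not isinstance(value, str):
                raise ConfigError(f"{path}: parameter {key} must be a string")
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"{path}: parameter {key} must be a number")

    try:
        params = ModelParameters(**{k: v for k, v in raw_params.items()})
        params.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from None

    qs_sum = raw_init["qs_bl_ini"] + raw_init["qs_rest_ini"]
    if not math.isclose(qs_sum, raw_init["qs_tot_ini"], rel_tol=0.1):
        logger.warning(
            "%s: qs_bl_ini + qs_rest_ini = %.4g differs from qs_tot_ini = %.4g",
            path,
            qs_sum,
            raw_init["qs_tot_ini"],
        )
    try:
        init = initial_state_from(
            params,
            tdw_ini=raw_init["tdw_ini"],
            ldw_bl_ini=raw_init["ldw_bl_ini"],
            qs_bl_ini=raw_init["qs_bl_ini"],
            qs_rest_ini=raw_init["qs_rest_ini"],
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    return params, init


def save_config(
    params: ModelParameters, init: PlantState, path: str | Path
) -> None:
    """Write a configuration TOML that :func:`load_config` reads back exactly."""
    path = Path(path)
    lines = [f"schema_version = {SCHEMA_VERSION}", "", "[parameters]"]
    for f in dataclasses.fields(ModelParameters):
        value = getattr(params, f.name)
        lines.append(f"{f.name} = {_toml_value(value)}")
    lines += ["", "[initial_state]"]
    init_values = {
        "la0": params.la0,
        "tdw_ini": init.tdw,
        "dw_fl_ini": init.ldw_fl,
        "ldw_bl_ini": init.ldw_bl,
        "qs_tot_ini": init.qs_tot,
        "a_qs": params.a_qs,
        "b_qs": params.b_qs,
        "qs_bl_ini": init.qs_bl,
        "qs_rest_ini": init.qs_rest,
    }
    for key in INITIAL_STATE_KEYS:
        lines.append(f"{key} = {_toml_value(init_values[key])}")
    path.write_text("\n".join(lines) + "\n")


def _toml_value(value) -> str:
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, float):
        text = repr(value)
        # TOML floats need a decimal point or exponent
        if "e" not in text and "." not in text and "n" not in text:
            text += ".0"
        return text
    return str(value)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged configuration fixture."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return Path(str(resources.files("sulfosim").joinpath("data", f"{name}.toml")))


def load_fixture(name: str) -> tuple[ModelParameters, PlantState]:
    """Load one of the packaged experiment configurations."""
    return load_config(fixture_path(name))
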