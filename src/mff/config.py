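"""YAML configuration loading for the fusion pipeline.

The configuration mirrors :class:`mff.pipeline.FusionConfig`; unspecified
keys fall back to the reference defaults (alpha=1, beta=0.89, gamma=0.31,
zeta1=4, eps=1e-6, s=4, L=9).  Unknown keys raise with a close-match
suggestion so typos never silently revert to defaults.
"""

from __future__ import annotations

import difflib
from pathlib import Path
from typing import Any, Mapping

import yaml

from .colorspace import GaussianSpec
from .gdfgf import GDFGFParams
from .pipeline import FusionConfig, MorphParams
from .saliency import SaliencyParams
from .weighting import ExponentParams

__all__ = ["ConfigError", "default_config_dict", "load_config", "config_to_dict"]


class ConfigError(ValueError):
    """A malformed or out-of-range configuration value."""


def default_config_dict() -> dict:
    """The full default configuration as a plain nested dict."""
    return config_to_dict(FusionConfig())


def config_to_dict(cfg: FusionConfig) -> dict:
    return {
        "exponents": {
            "alpha": cfg.exponents.alpha,
            "beta": cfg.exponents.beta,
            "gamma": cfg.exponents.gamma,
        },
        "saliency": {
            "sigma_c": cfg.saliency.sigma_c,
            "sigma_d": cfg.saliency.sigma_d,
            "bandpass": cfg.saliency.bandpass,
            "omega0": cfg.saliency.omega0,
            "sigma_f": cfg.saliency.sigma_f,
            "smooth_sigma": cfg.saliency.smooth.sigma,
            "smooth_radius": cfg.saliency.smooth.effective_radius,
        },
        "filter": {
            "zeta1_1": cfg.filter_pass1.zeta1,
            "eps_1": cfg.filter_pass1.eps,
            "zeta1_2": cfg.filter_pass2.zeta1,
            "eps_2": cfg.filter_pass2.eps,
            "s": cfg.filter_pass1.s,
            "L": cfg.filter_pass1.L,
            "reg_form": cfg.filter_pass1.reg_form,
        },
        "morphology": {
            "threshold": cfg.morph.threshold,
            "min_area": cfg.morph.min_area,
            "apply_to": cfg.morph_apply_to,
        },
        "decomposition": {
            "sigma": cfg.decomposition.sigma,
            "radius": cfg.decomposition.effective_radius,
        },
        "detail_guidance": cfg.detail_guidance,
    }


def _check_keys(given: Mapping[str, Any], allowed: set[str], context: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {context}{suffix}")


def _merge(overrides: Mapping[str, Any] | None) -> FusionConfig:
    data = default_config_dict()
    overrides = overrides or {}
    _check_keys(overrides, set(data), "config")
    for section, values in overrides.items():
        if section == "detail_guidance":
            data[section] = values
            continue
        if not isinstance(values, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        _check_keys(values, set(data[section]), f"config section {section!r}")
        data[section].update(values)

    try:
        return FusionConfig(
            exponents=ExponentParams(**data["exponents"]),
            saliency=SaliencyParams(
                sigma_c=data["saliency"]["sigma_c"],
                sigma_d=data["saliency"]["sigma_d"],
                bandpass=data["saliency"]["bandpass"],
                omega0=data["saliency"]["omega0"],
                sigma_f=data["saliency"]["sigma_f"],
                smooth=GaussianSpec(
                    sigma=data["saliency"]["smooth_sigma"],
                    radius=data["saliency"]["smooth_radius"],
                ),
            ),
            filter_pass1=GDFGFParams(
                zeta1=data["filter"]["zeta1_1"],
                eps=data["filter"]["eps_1"],
                s=data["filter"]["s"],
                L=data["filter"]["L"],
                reg_form=data["filter"]["reg_form"],
            ),
            filter_pass2=GDFGFParams(
                zeta1=data["filter"]["zeta1_2"],
                eps=data["filter"]["eps_2"],
                s=data["filter"]["s"],
                L=data["filter"]["L"],
                reg_form=data["filter"]["reg_form"],
            ),
            morph=MorphParams(
                threshold=data["morphology"]["threshold"],
                min_area=data["morphology"]["min_area"],
            ),
            decomposition=GaussianSpec(
                sigma=data["decomposition"]["sigma"],
                radius=data["decomposition"]["radius"],
            ),
            detail_guidance=data["detail_guidance"],
            morph_apply_to=data["morphology"]["apply_to"],
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> FusionConfig:
    """Build a :class:`FusionConfig` from defaults, an optional YAML file,
    and programmatic overrides (highest precedence)."""
    file_data: dict = {}
    if path is not None:
        path = Path(path)
        try:
            loaded = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config file {path} must contain a mapping")
            file_data = loaded
    merged: dict = {}
    for src in (file_data, overrides or {}):
        for key, val in src.items():
            if isinstance(val, Mapping) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            elif isinstance(val, Mapping):
                merged[key] = dict(val)
            else:
                merged[key] = val
    return _merge(merged)
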