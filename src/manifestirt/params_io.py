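"""JSON parameter files: schema validation, loading, and exact round-trip.

Layout: {"model": "hm" | "sm" | "dm", "items": [...], "kernel": {...}}.
Item fields per model -- hm: alpha, beta, phi, xi; sm: beta, d;
dm: alpha, beta, t_er (optional, shared default 0).  The kernel is either
the generic {"mean": [...], "cov": [[...]]} or the model shorthand
({"rho", "v_eta2"} for hm; {"m", "v2"} for sm/dm, defaulting to N(0, 1)).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .dm import DMItem
from .errors import ParameterError
from .expfam import KernelSpec
from .hm import HMItem, HMKernel
from .sm import SMItem

__all__ = ["load_params", "dump_params", "parse_params"]

_ITEM_FIELDS = {
    "hm": {"alpha", "beta", "phi", "xi"},
    "sm": {"beta", "d"},
    "dm": {"alpha", "beta"},  # t_er optional
}


def _require_number(obj: dict, key: str, where: str) -> float:
    if key not in obj:
        raise ParameterError(f"{where}: missing required field '{key}'")
    val = obj[key]
    if isinstance(val, bool) or not isinstance(val, (int, float)):
        raise ParameterError(f"{where}: field '{key}' must be a number, got {val!r}")
    return float(val)


def _parse_kernel(model: str, obj: dict):
    if model == "hm":
        if "rho" in obj or "v_eta2" in obj:
            rho = _require_number(obj, "rho", "kernel")
            v_eta2 = _require_number(obj, "v_eta2", "kernel")
            try:
                return HMKernel(rho=rho, v_eta2=v_eta2)
            except ValueError as exc:
                raise ParameterError(f"kernel: {exc}") from exc
        raise ParameterError("kernel: hm requires fields 'rho' and 'v_eta2'")
    if "mean" in obj or "cov" in obj:
        try:
            return KernelSpec(mean=np.asarray(obj["mean"], dtype=float),
                              cov=np.asarray(obj["cov"], dtype=float))
        except (KeyError, ValueError) as exc:
            raise ParameterError(f"kernel: {exc}") from exc
    m = _require_number(obj, "m", "kernel") if "m" in obj else 0.0
    v2 = _require_number(obj, "v2", "kernel") if "v2" in obj else 1.0
    if v2 <= 0:
        raise ParameterError("kernel: 'v2' must be positive")
    return KernelSpec(mean=np.array([m]), cov=np.array([[v2]]))


def _parse_item(model: str, obj: dict, index: int):
    where = f"items[{index}]"
    if not isinstance(obj, dict):
        raise ParameterError(f"{where}: expected an object")
    for key in _ITEM_FIELDS[model]:
        _require_number(obj, key, where)
    try:
        if model == "hm":
            return HMItem(alpha=float(obj["alpha"]), beta=float(obj["beta"]),
                          phi=float(obj["phi"]), xi=float(obj["xi"]))
        if model == "sm":
            return SMItem(beta=float(obj["beta"]), d=float(obj["d"]))
        return DMItem(alpha=float(obj["alpha"]), beta=float(obj["beta"]),
                      t_er=float(obj.get("t_er", 0.0)))
    except ValueError as exc:
        raise ParameterError(f"{where}: {exc}") from exc


def parse_params(payload: dict):
    """Validate a parsed JSON payload; returns (model, items, kernel)."""
    if not isinstance(payload, dict):
        raise ParameterError("parameter file must contain a JSON object")
    model = payload.get("model")
    if model not in ("hm", "sm", "dm"):
        raise ParameterError("field 'model' must be one of 'hm', 'sm', 'dm'")
    items_raw = payload.get("items")
    if not isinstance(items_raw, list) or not items_raw:
        raise ParameterError("field 'items' must be a non-empty list")
    items = tuple(_parse_item(model, obj, i) for i, obj in enumerate(items_raw))
    kernel_raw = payload.get("kernel")
    if model == "hm" and kernel_raw is None:
        raise ParameterError("field 'kernel' is required for model 'hm'")
    kernel = _parse_kernel(model, kernel_raw or {})
    return model, items, kernel


def load_params(path):
    """Load and validate a parameter JSON file."""
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParameterError(f"{path}: invalid JSON ({exc})") from exc
    return parse_params(payload)


def dump_params(model: str, items, kernel, path) -> None:
    """Serialize parameters back to JSON; floats round-trip bit-exactly
    (shortest-repr encoding of IEEE doubles)."""
    if model == "hm":
        items_obj = [{"alpha": it.alpha, "beta": it.beta, "phi": it.phi,
                      "xi": it.xi} for it in items]
        kernel_obj = {"rho": kernel.rho, "v_eta2": kernel.v_eta2}
    elif model == "sm":
        items_obj = [{"beta": it.beta, "d": it.d} for it in items]
        kernel_obj = {"m": float(kernel.mean[0]), "v2": float(kernel.cov[0, 0])}
    elif model == "dm":
        items_obj = [{"alpha": it.alpha, "beta": it.beta, "t_er": it.t_er}
                     for it in items]
        kernel_obj = {"m": float(kernel.mean[0]), "v2": float(kernel.cov[0, 0])}
    else:
        raise ParameterError("model must be one of 'hm', 'sm', 'dm'")
    payload = {"model": model, "items": items_obj, "kernel": kernel_obj}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
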