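"""Key-value configuration for thresholds and defaults.

A config file is plain text, one ``key = value`` per line, ``#`` comments.
Values are parsed as int, float, bool, a comma-separated pair of floats
(used for melted-pair intervals, e.g. ``melted.buckle = -35, 35``) or a
bare string.  Command-line flags override config values, which override
the package defaults below.
"""

from __future__ import annotations

from .conformation import DEFAULT_MELTED_RANGES

DEFAULTS: dict[str, object] = {
    "max_free": 2,
    "k": 35,
    "smooth_window": 10,
    "tau_min": 1e-3,
    "min_palindrome": 4,
    "motif_radius": 5,
    **{f"melted.{name}": rng for name, rng in DEFAULT_MELTED_RANGES.items()},
}


def _parse_value(raw: str):
    raw = raw.strip()
    if "," in raw:
        parts = [p.strip() for p in raw.split(",")]
        try:
            return tuple(float(p) for p in parts)
        except ValueError:
            pass
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def load_config(path=None) -> dict[str, object]:
    """Package defaults merged with an optional key=value file."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = line.split("=", 1)
            cfg[key.strip()] = _parse_value(raw)
    return cfg


def melted_ranges(cfg: dict[str, object]) -> dict[str, tuple[float, float]]:
    """Extract the per-parameter melted-pair intervals from a config map."""
    out = {}
    for key, val in cfg.items():
        if key.startswith("melted."):
            name = key.split(".", 1)[1]
            if not (isinstance(val, tuple) and len(val) == 2):
                raise ValueError(f"config {key} must be 'low, high', got {val!r}")
            out[name] = (float(val[0]), float(val[1]))
    return out
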