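"""Flat ``key = value`` configuration files mirroring the CLI thresholds."""

from __future__ import annotations

from pathlib import Path

DEFAULTS: dict[str, object] = {
    "bin_size": 5000,
    "min_distance": 1000,
    "aqua_cpm_threshold": 0.0,
    "proximal_window": 5000,
    "long_range_min": 25_000,
    "long_range_max": 3_000_000,
    "l2fc_epsilon": 0.5,
    "apa_flank": 10,
    "apa_bin_size": 5000,
    "pulr_numerator": "pre_tes",
    "drop_duplicates": False,
}


def _coerce(value: str):
    low = value.strip()
    if low.lower() in ("true", "false"):
        return low.lower() == "true"
    for cast in (int, float):
        try:
            return cast(low)
        except ValueError:
            pass
    return low


def load_config(path: str | Path | None) -> dict[str, object]:
    """Read a key = value file on top of the built-in defaults."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        cfg[key] = _coerce(value)
    return cfg
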