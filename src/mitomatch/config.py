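"""Plain-text key=value run configuration.

Example::

    # 300K constant scenario, Oversti rates
    scenario = constant
    n_females = 50000
    n_generations = 1200
    live_generations = 3
    include_males = true
    scheme = oversti
    seed = 1
    n_genealogies = 1
    n_mutation_reps = 1
    n_pois = 10000
    meioses_fraction = 0.1

``scenario`` may also name a canonical scenario directly:
``300K_const``, ``1.2M_const`` or ``1.2M_growth``.
"""
from __future__ import annotations

from .demography import (
    CANONICAL_SCENARIOS,
    DemographyScenario,
    build_constant_sizes,
    build_growth_sizes,
)

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_config(path) -> dict:
    """Parse a key=value file (blank lines and ``#`` comments ignored)."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = line.split("=", 1)
            cfg[key.strip().lower()] = value.strip()
    return cfg


def scenario_from_config(cfg: dict) -> DemographyScenario:
    kind = cfg.get("scenario", "constant")
    common = {}
    if "live_generations" in cfg:
        common["n_live_generations"] = int(cfg["live_generations"])
    if "include_males" in cfg:
        common["include_males"] = _BOOL[cfg["include_males"].lower()]
    if kind in CANONICAL_SCENARIOS:
        scenario = CANONICAL_SCENARIOS[kind]()
        for k, v in common.items():
            setattr(scenario, k, v)
        return scenario
    if kind == "constant":
        return build_constant_sizes(
            int(cfg["n_females"]),
            int(cfg["n_generations"]),
            label=cfg.get("label", ""),
            **common,
        )
    if kind == "growth":
        return build_growth_sizes(
            int(cfg["n_initial"]),
            float(cfg["growth_rate"]),
            int(cfg["n_constant"]),
            int(cfg["n_growth"]),
            exact_final=int(cfg["exact_final"]) if "exact_final" in cfg else None,
            label=cfg.get("label", ""),
            **common,
        )
    raise ValueError(f"unknown scenario kind {kind!r}")


def protocol_kwargs_from_config(cfg: dict) -> dict:
    """Protocol-level settings (replication counts, PoI draws, seed)."""
    out = {}
    for key, cast in (
        ("n_genealogies", int),
        ("n_mutation_reps", int),
        ("n_pois", int),
        ("meioses_fraction", float),
        ("seed", int),
    ):
        if key in cfg:
            out[key] = cast(cfg[key])
    return out
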