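"""CSV schemas, run configuration and pipeline dispatch with provenance.

All interchange is CSV with unit-bearing column names (time_h, conc_uM, ...).
Readers match headers case-insensitively and order-insensitively, tolerate
extra columns (carried through with a warning) and report unparsable cells
with their line number.  ``run_pipeline`` executes one named stage from a
:class:`RunConfig` and writes a provenance sidecar (stage, parameters, seed,
package version, input/output checksums) next to each output, so identical
config + seed reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import ecology_model as em
from .errors import InvalidArgumentError, SchemaError

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "read_table",
    "write_table",
    "load_config",
    "run_pipeline",
]

#: column -> dtype kind ("num" or "str") per schema; order defines output order.
SCHEMAS: Dict[str, Dict[str, str]] = {
    "culture": {
        "time_h": "num",
        "live_per_ml": "num",
        "dead_per_ml": "num",
        "metabolite_fmole_per_ml": "num",
    },
    "coculture": {
        "time_h": "num",
        "generation": "num",
        "releaser_per_ml": "num",
        "consumer_per_ml": "num",
        "orgs_fmole_per_ml": "num",
        "ratio": "num",
    },
    "chromatogram": {"rt_min": "num", "signal": "num"},
    "plate": {"compound": "str", "conc_uM": "num", "replicate": "num", "od600": "num"},
    "trajectory": {"generation": "num", "count_a": "num", "count_b": "num"},
    "fluorescence": {"time_h": "num", "norm_intensity": "num"},
    "screen": {
        "size_class": "str",
        "colonies_counted": "num",
        "screened": "num",
        "auxotrophs_found": "num",
    },
    "standards": {"conc_uM": "num", "response": "num"},
    "rate_curve": {"conc_uM": "num", "rate_per_h": "num"},
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV against a named schema.

    Headers are matched case-insensitively and in any order; missing columns
    raise :class:`SchemaError` naming the column; extra columns are kept
    with a warning; a cell that fails numeric parsing raises an error
    naming the column and line.
    """
    if schema not in SCHEMAS:
        raise InvalidArgumentError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    lower_map = {c.lower(): c for c in raw.columns}
    out = {}
    for col, kind in spec.items():
        src = lower_map.get(col.lower())
        if src is None:
            raise SchemaError(f"{path}: missing column '{col}' for schema '{schema}'")
        series = raw[src]
        if kind == "num":
            parsed = pd.to_numeric(series, errors="coerce")
            bad = parsed.isna() & series.notna() & (series.str.strip() != "")
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"{path}: column '{col}', line {row + 2}: "
                    f"cannot parse {series[row]!r} as a number"
                )
            out[col] = parsed
        else:
            out[col] = series
    known = {c.lower() for c in spec}
    extras = [c for c in raw.columns if c.lower() not in known]
    if extras:
        warnings.warn(f"{path}: extra columns carried through: {extras}")
        for c in extras:
            out[c] = raw[c]
    return pd.DataFrame(out)


def write_table(frame: pd.DataFrame, path, schema: Optional[str] = None) -> None:
    """Write a CSV, schema columns first when a schema is named."""
    if schema is not None:
        spec = SCHEMAS[schema]
        missing = [c for c in spec if c not in frame.columns]
        if missing:
            raise SchemaError(f"cannot write schema '{schema}': missing {missing}")
        ordered = list(spec) + [c for c in frame.columns if c not in spec]
        frame = frame[ordered]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


_CONFIG_KEYS = {"stage", "params", "inputs", "outputs", "seed", "log_level"}

#: parameter names (unit-suffixed) each stage accepts.
STAGE_PARAMS: Dict[str, set] = {
    "synth": {
        "kind",
        "reservoir_conc_uM",
        "duration_h",
        "step_h",
        "relative_sd",
        "additive_sd",
        "death_rate_per_h",
        "limitation",
        "r_fmole_per_cell_h",
        "c_fmole_per_cell",
        "doubling_time_h",
        "growth_rate_per_h",
        "switch_time_h",
        "init_ratio",
        "n_generations",
        "sampling_counts",
        "total_density_per_ml",
        "curve_slope_od_per_uM",
        "blank_od",
        "saturation_od",
        "concs_uM",
        "replicates",
        "compounds",
        "peak_rt_min",
        "peak_amplitude",
        "peak_sigma_min",
        "baseline_slope_per_min",
        "baseline_intercept",
    },
    "simulate": {
        "r_fmole_per_cell_h",
        "c_fmole_per_cell",
        "doubling_time_h",
        "gmax_consumer_per_h",
        "K_half_fmole_per_ml",
        "init_ratio",
        "total_density_per_ml",
        "duration_h",
        "step_h",
        "mode",
    },
    "release-rate": {"doubling_time_h", "dil_per_h", "window_start_h", "window_end_h"},
    "quantify-hplc": {"window_start_min", "window_end_min"},
    "bioassay": {"mode", "linear_range_lo_uM", "linear_range_hi_uM", "compound"},
    "growth": {"window_points", "cutoff_fraction"},
    "fitness": set(),
    "screen": set(),
}


@dataclass
class RunConfig:
    """One pipeline stage with its parameters, paths and seed."""

    stage: str
    params: Dict = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.stage not in STAGE_PARAMS:
            raise SchemaError(f"unknown stage {self.stage!r}")
        allowed = STAGE_PARAMS[self.stage]
        unknown = set(self.params) - allowed
        if unknown:
            raise SchemaError(
                f"stage '{self.stage}': unknown parameters {sorted(unknown)} "
                f"(allowed: {sorted(allowed)})"
            )


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError("config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    if "stage" not in data:
        raise SchemaError("config requires a 'stage' key")
    return RunConfig(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(config: RunConfig) -> None:
    from . import __version__

    record = {
        "stage": config.stage,
        "params": config.params,
        "seed": config.seed,
        "version": __version__,
        "inputs": {k: _sha256(v) for k, v in config.inputs.items()},
        "outputs": {k: _sha256(v) for k, v in config.outputs.items()},
    }
    for out_path in config.outputs.values():
        sidecar = Path(str(out_path) + ".prov.json")
        sidecar.write_text(json.dumps(record, indent=2, sort_keys=True))


def _params_from_config(p: Dict) -> em.EcologyParams:
    g = em.dilution_rate(p.get("doubling_time_h", 8.0))
    return em.EcologyParams(
        r=p.get("r_fmole_per_cell_h", 0.02),
        c=p.get("c_fmole_per_cell", 2.0),
        g=g,
        dil=g,
        gmax_consumer=p.get("gmax_consumer_per_h", 0.35),
        K_half=p.get("K_half_fmole_per_ml", 1.0e5),
    )


def _stage_synth(config: RunConfig) -> None:
    from . import synthetic_data as sd

    p = config.params
    kind = p.get("kind", "chemostat")
    noise = sd.NoiseSpec(
        relative_sd=p.get("relative_sd", 0.0),
        additive_sd=p.get("additive_sd", 0.0),
        seed=config.seed,
    )
    out = config.outputs["table"]
    if kind == "chemostat":
        series = sd.gen_chemostat_series(
            _params_from_config(p),
            reservoir_conc=p.get("reservoir_conc_uM", 21.0),
            duration=p.get("duration_h", 120.0),
            step=p.get("step_h", 1.0),
            noise=noise,
            death_rate=p.get("death_rate_per_h"),
            limitation=p.get("limitation", "lysine"),
        )
        write_table(series.to_frame(), out, "culture")
    elif kind == "chromatogram":
        spec = sd.ChromatogramSpec(
            peaks=((p.get("peak_rt_min", 7.0), p.get("peak_amplitude", 100.0),
                    p.get("peak_sigma_min", 0.05)),),
            baseline_slope=p.get("baseline_slope_per_min", 0.0),
            baseline_intercept=p.get("baseline_intercept", 0.0),
        )
        write_table(sd.gen_chromatogram(spec, noise), out, "chromatogram")
    elif kind == "plate":
        plate = sd.gen_bioassay_plate(
            curve_slope=p.get("curve_slope_od_per_uM", 0.4),
            blank_od=p.get("blank_od", 0.05),
            saturation_od=p.get("saturation_od", 1.2),
            concs=p.get("concs_uM", [0.0, 0.25, 0.5, 1.0, 2.0]),
            replicates=p.get("replicates", 3),
            noise=noise,
            compounds=p.get("compounds", ["GSH"]),
        )
        write_table(plate, out, "plate")
    elif kind == "competition":
        traj = sd.gen_competition(
            _params_from_config(p),
            init_ratio=p.get("init_ratio", 1.0),
            n_generations=p.get("n_generations", 40),
            sampling_counts=p.get("sampling_counts", 10_000),
            noise=noise,
            total_density=p.get("total_density_per_ml", 3.0e6),
        )
        write_table(traj.to_frame(), out, "trajectory")
    elif kind == "fluorescence":
        series = sd.gen_fluorescence_series(
            growth_rate=p.get("growth_rate_per_h", 0.2),
            death_rate=p.get("death_rate_per_h", 0.0),
            switch_time=p.get("switch_time_h", 24.0),
            duration=p.get("duration_h", 48.0),
            step=p.get("step_h", 0.5),
            noise=noise,
        )
        write_table(series.to_frame(), out, "fluorescence")
    else:
        raise InvalidArgumentError(f"unknown synth kind {kind!r}")


def _stage_simulate(config: RunConfig) -> None:
    p = config.params
    params = _params_from_config(p)
    total = p.get("total_density_per_ml", 3.0e6)
    ratio = p.get("init_ratio", 1.0)
    C0 = total * ratio / (1.0 + ratio)
    traj = em.simulate_coculture(
        params,
        em.CocultureState(R=total - C0, C=C0, O=em.steady_state_organosulfur(params)),
        duration=p.get("duration_h", 480.0),
        step=p.get("step_h", 1.0),
        mode=p.get("mode", "serial"),
    )
    write_table(traj, config.outputs["table"], "coculture")


def _stage_release_rate(config: RunConfig) -> None:
    p = config.params
    series = em.CultureSeries.from_frame(read_table(config.inputs["culture"], "culture"))
    dil = p.get("dil_per_h")
    if dil is None:
        dil = em.dilution_rate(p.get("doubling_time_h", 8.0))
    window = None
    if "window_start_h" in p or "window_end_h" in p:
        window = (
            p.get("window_start_h", float(series.time[0])),
            p.get("window_end_h", float(series.time[-1])),
        )
    rate = em.estimate_release_rate(series, dil, window)
    out = config.outputs["table"]
    write_table(pd.DataFrame({"release_rate_fmole_per_cell_h": [rate]}), out)


def _stage_quantify_hplc(config: RunConfig) -> None:
    from . import hplc_quant as hq

    p = config.params
    window = (p.get("window_start_min", 6.5), p.get("window_end_min", 8.0))
    chrom = hq.Chromatogram.from_frame(
        read_table(config.inputs["chromatogram"], "chromatogram")
    )
    standards = read_table(config.inputs["standards"], "standards")
    curve = hq.fit_standard_curve(
        list(zip(standards["conc_uM"], standards["response"]))
    )
    q = hq.quantify_chromatogram(chrom, curve, window)
    write_table(
        pd.DataFrame(
            {
                "peak_rt_min": [q.peak_rt],
                "area": [q.area],
                "conc_uM": [q.concentration],
                "flags": [";".join(q.flags) or "ok"],
            }
        ),
        config.outputs["table"],
    )


def _stage_bioassay(config: RunConfig) -> None:
    from . import bioassay as ba
    from . import kinetics_fitness as kf

    p = config.params
    mode = p.get("mode", "yield")
    if mode == "yield":
        standards = read_table(config.inputs["standards"], "plate")
        rng = (p.get("linear_range_lo_uM", 0.0), p.get("linear_range_hi_uM", 2.0))
        curve = ba.fit_yield_curve(standards, p.get("compound", "GSH"), rng)
        unknowns = read_table(config.inputs["unknowns"], "plate")
        results = [ba.infer_gsh_equivalents(od, curve) for od in unknowns["od600"]]
        frame = unknowns.copy()
        frame["gsh_equiv_uM"] = [r.estimate for r in results]
        frame["flags"] = [r.flag for r in results]
        write_table(frame, config.outputs["table"])
    elif mode == "rate":
        curve = read_table(config.inputs["rate_curve"], "rate_curve")
        series = kf.FluorescenceSeries.from_frame(
            read_table(config.inputs["fluorescence"], "fluorescence")
        )
        result = ba.rate_bioassay(
            series, list(zip(curve["conc_uM"], curve["rate_per_h"]))
        )
        write_table(
            pd.DataFrame({"equiv_uM": [result.estimate], "flags": [result.flag]}),
            config.outputs["table"],
        )
    else:
        raise InvalidArgumentError(f"unknown bioassay mode {mode!r}")


def _stage_growth(config: RunConfig) -> None:
    from . import kinetics_fitness as kf

    p = config.params
    series = kf.FluorescenceSeries.from_frame(
        read_table(config.inputs["fluorescence"], "fluorescence")
    )
    rate = kf.max_growth_rate(
        series, p.get("window_points", 4), p.get("cutoff_fraction", 0.25)
    )
    metrics = kf.death_metrics(series)
    write_table(
        pd.DataFrame(
            {
                "max_growth_rate_per_h": [rate],
                "endpoint_survival": [metrics.endpoint_survival],
                "death_rate_per_h": [metrics.death_rate],
                "flags": [metrics.flag or "ok"],
            }
        ),
        config.outputs["table"],
    )


def _stage_fitness(config: RunConfig) -> None:
    from . import kinetics_fitness as kf

    traj = kf.RatioTrajectory.from_frame(
        read_table(config.inputs["trajectory"], "trajectory")
    )
    result = kf.competition_fitness(traj)
    write_table(
        pd.DataFrame(
            {
                "relative_fitness": [result.relative_fitness],
                "window_start_index": [result.window_start_index],
                "start_fraction": [result.start_fraction],
            }
        ),
        config.outputs["table"],
    )


def _stage_screen(config: RunConfig) -> None:
    from . import kinetics_fitness as kf

    table = read_table(config.inputs["screen"], "screen")
    freq = kf.auxotroph_frequency(
        kf.ColonyClassCount(
            int(row.colonies_counted), int(row.screened), int(row.auxotrophs_found)
        )
        for row in table.itertuples()
    )
    write_table(pd.DataFrame({"auxotroph_frequency": [freq]}), config.outputs["table"])


_STAGES: Dict[str, Callable[[RunConfig], None]] = {
    "synth": _stage_synth,
    "simulate": _stage_simulate,
    "release-rate": _stage_release_rate,
    "quantify-hplc": _stage_quantify_hplc,
    "bioassay": _stage_bioassay,
    "growth": _stage_growth,
    "fitness": _stage_fitness,
    "screen": _stage_screen,
}


def run_pipeline(config: RunConfig) -> int:
    """Execute one stage and write provenance sidecars; returns 0 on success."""
    _STAGES[config.stage](config)
    _write_provenance(config)
    return 0
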