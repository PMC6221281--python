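"""Readers, writers, run manifests, and fixture generation.

Canonical output formats are CSV and JSON.  A batch is written as

``batch_result.json``
    config echo plus pooled censuses per snapshot cycle.
``batch_result.csv``
    long format with columns setting, experiment, cycle, k, count,
    proportion (``experiment = "pooled"`` rows carry the pooled census).
``manifest.json``
    tool version, full config, root seed and seeding protocol, and the
    output file inventory — enough to reproduce the run bit-for-bit.

Empirical reference tables are CSV with columns ``organism, k,
proportion`` (k = 4..9); chi-square results are CSV with columns
``setting, organism, sheet1, sheet2`` (blank = undefined).  An optional
two-sheet spreadsheet export mirrors that layout (requires openpyxl).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from pathlib import Path

import pandas as pd

from .fitstats import (
    FIT_K_RANGE,
    Chi2Result,
    EmpiricalReference,
    PolygonDistribution,
)
from .simulator import BatchResult, SimulationConfig, setting_name
from .strategies import CHOICE2_OPTIONS, StrategyConfig, side2_pmf
from .tissue import tissue_to_json

__all__ = [
    "write_batch_result",
    "read_batch_result",
    "write_empirical_table",
    "read_empirical_table",
    "write_chi2_results",
    "read_chi2_results",
    "write_spreadsheet",
    "config_to_dict",
    "config_from_dict",
    "generate_fixtures",
]

TOOL_VERSION = "0.1.0"


# -- configuration round-trip -------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["snapshot_cycles"] = sorted(config.snapshot_cycles)
    d["strategy"] = {k: v for k, v in d["strategy"].items() if v is not None}
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    strat = d.pop("strategy", {})
    snaps = d.pop("snapshot_cycles", None)
    return SimulationConfig(
        strategy=StrategyConfig(**strat),
        snapshot_cycles=frozenset(snaps) if snaps is not None else None,
        **{k: v for k, v in d.items() if k in ("initial_sides", "cycles", "batch_size", "seed")},
    )


# -- batch results ------------------------------------------------------------

def _census_rows(setting: str, experiment, census: PolygonDistribution):
    for k in sorted(census.counts):
        yield {
            "setting": setting,
            "experiment": experiment,
            "cycle": None,  # filled by caller
            "k": k,
            "count": census.counts[k],
            "proportion": census.proportion(k),
        }


def write_batch_result(batch: BatchResult, outdir) -> list[Path]:
    """Write one batch to ``outdir`` (created if needed); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = setting_name(batch.config)

    rows = []
    for e in batch.experiments:
        for cycle, census in sorted(e.snapshots.items()):
            for row in _census_rows(name, e.experiment_index, census):
                row["cycle"] = cycle
                rows.append(row)
    for cycle, census in sorted(batch.pooled.items()):
        for row in _census_rows(name, "pooled", census):
            row["cycle"] = cycle
            rows.append(row)
    csv_path = outdir / "batch_result.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)

    payload = {
        "setting": name,
        "config": config_to_dict(batch.config),
        "pooled": {
            str(cycle): census.counts for cycle, census in sorted(batch.pooled.items())
        },
        "experiments": [
            {
                "experiment_index": e.experiment_index,
                "final_cells": e.final_cells,
                "final_mean_sides": e.final_mean_sides,
                "n_divisions": e.n_divisions,
            }
            for e in batch.experiments
        ],
    }
    json_path = outdir / "batch_result.json"
    json_path.write_text(json.dumps(payload, indent=1))

    manifest = {
        "tool": "epitopo",
        "version": TOOL_VERSION,
        "setting": name,
        "config": config_to_dict(batch.config),
        "root_seed": batch.config.seed,
        "seeding": "numpy SeedSequence(root_seed).spawn(batch_size); "
        "experiment j uses child j",
        "written_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [csv_path.name, json_path.name],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return [csv_path, json_path, manifest_path]


def read_batch_result(outdir) -> tuple[SimulationConfig, dict[int, PolygonDistribution]]:
    """Read back a written batch: (config, pooled censuses by cycle)."""
    payload = json.loads((Path(outdir) / "batch_result.json").read_text())
    config = config_from_dict(payload["config"])
    pooled = {
        int(cycle): PolygonDistribution({int(k): int(c) for k, c in counts.items()})
        for cycle, counts in payload["pooled"].items()
    }
    return config, pooled


# -- empirical reference tables ----------------------------------------------

def write_empirical_table(refs: list[EmpiricalReference], path) -> Path:
    path = Path(path)
    rows = [
        {"organism": r.organism, "k": k, "proportion": r.proportions[k]}
        for r in refs
        for k in FIT_K_RANGE
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_empirical_table(path) -> dict[str, EmpiricalReference]:
    """Read a reference table; raises with row numbers on malformed input."""
    df = pd.read_csv(path)
    required = {"organism", "k", "proportion"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"empirical table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = df[(df["proportion"] < 0) | (df["proportion"] > 1) | df["proportion"].isna()]
    if len(bad):
        rows = [int(r) + 2 for r in bad.index]  # 1-based, plus header line
        raise ValueError(f"invalid proportions in empirical table at file rows {rows}")
    refs: dict[str, EmpiricalReference] = {}
    for organism, grp in df.groupby("organism", sort=False):
        ks = set(int(k) for k in grp["k"])
        missing = set(FIT_K_RANGE) - ks
        if missing:
            raise ValueError(
                f"organism {organism!r} is missing k rows {sorted(missing)}"
            )
        props = {int(row.k): float(row.proportion) for row in grp.itertuples()}
        refs[str(organism)] = EmpiricalReference(str(organism), props)
    if not refs:
        raise ValueError("empirical table contains no organisms")
    return refs


# -- chi-square results -------------------------------------------------------

def write_chi2_results(results: list[Chi2Result], path) -> Path:
    path = Path(path)
    rows = [
        {
            "setting": r.setting,
            "organism": r.organism,
            "sheet1": r.sheet1 if r.sheet1_defined else None,
            "sheet2": r.sheet2 if r.sheet2_defined else None,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_chi2_results(path) -> list[Chi2Result]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples():
        s1 = float(row.sheet1) if not pd.isna(row.sheet1) else math.nan
        s2 = float(row.sheet2) if not pd.isna(row.sheet2) else math.nan
        out.append(Chi2Result(str(row.organism), str(row.setting), s1, s2))
    return out


def write_spreadsheet(results: list[Chi2Result], path) -> Path:
    """Two-sheet spreadsheet export ("Sheet 1" empirical denominators,
    "Sheet 2" simulation denominators).  Requires openpyxl."""
    path = Path(path)
    frames = {
        "Sheet 1": pd.DataFrame(
            [{"setting": r.setting, "organism": r.organism, "chi2": r.sheet1} for r in results]
        ),
        "Sheet 2": pd.DataFrame(
            [{"setting": r.setting, "organism": r.organism, "chi2": r.sheet2} for r in results]
        ),
    }
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for sheet, frame in frames.items():
            frame.to_excel(writer, sheet_name=sheet, index=False)
    return path


# -- fixtures -----------------------------------------------------------------

FIXTURE_KINDS = ("reference-table", "toy-tissue", "pmf-table")

# Made-up proportions for two fictitious organisms (synthetic fixture data,
# not measurements); hexagon-dominated like real epithelia.
_SYNTHETIC_REFS = {
    "SyntheticA": {4: 0.03, 5: 0.27, 6: 0.45, 7: 0.19, 8: 0.05, 9: 0.01},
    "SyntheticB": {4: 0.05, 5: 0.30, 6: 0.40, 7: 0.17, 8: 0.06, 9: 0.02},
}


def generate_fixtures(kind: str, seed: int, outdir) -> list[Path]:
    """Deterministic fixture files for tests and documentation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "reference-table":
        refs = [EmpiricalReference(name, p) for name, p in _SYNTHETIC_REFS.items()]
        return [write_empirical_table(refs, outdir / "synthetic_reference_table.csv")]
    if kind == "toy-tissue":
        from .simulator import run_experiment

        config = SimulationConfig(
            strategy=StrategyConfig("RandN", "random", "Random"),
            initial_sides=7,
            cycles=2,
            batch_size=1,
            snapshot_cycles=frozenset({2}),
            seed=seed,
        )
        _, tissue = run_experiment(config, seed, return_tissue=True)
        path = outdir / "toy_tissue.json"
        path.write_text(tissue_to_json(tissue))
        return [path]
    if kind == "pmf-table":
        rows = []
        for choice2 in CHOICE2_OPTIONS:
            kwargs = {}
            if choice2 == "Even-Binomial":
                kwargs["probB"] = 0.3
            if choice2 in ("rotNorm", "rotTanNorm"):
                kwargs["stdbeta"] = 0.15
            cfg = StrategyConfig("RandN", choice2, "Random", **kwargs)
            for i in range(4, 13):
                pmf = side2_pmf(i, cfg)
                for u, p in zip(pmf.us, pmf.probabilities):
                    rows.append(
                        {"choice2": choice2, **kwargs, "i": i, "u": u, "probability": p}
                    )
        path = outdir / "side2_pmf_table.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return [path]
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
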