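"""File IO and pipeline orchestration.

Table dialects: cohort tables are comma-separated UTF-8 CSV with a mandatory
header and "NA" for missing values; tag matrices are TSV with tags as rows
and samples as columns, accompanied by a two-column sample-sex map. Every
pipeline run emits a JSON manifest (resolved parameters, paths, seed,
package version, timestamp) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohorts import IndividualRecord, tally_cohort
from .genetics import Genotype, InadmissiblePairError, classify_individual
from .markers import TagMatrix, screen_sex_markers
from .popdyn import (
    DemographicParams,
    PopulationState,
    Trajectory,
    simulate_trajectory,
    stable_distribution,
)
from .simulate import RadDesign, simulate_cross, simulate_native_population

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "id", "site", "phenotype", "gonopore_config",
    "w_band", "z_band", "genotype", "progeny",
]

_BOOL_MAP = {"true": True, "t": True, "1": True,
             "false": False, "f": False, "0": False}


def _parse_bool(value: Any, row: int, col: str) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "NA":
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise ValueError(f"row {row}, column {col!r}: cannot parse boolean {value!r}")


def records_to_frame(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "site": r.site,
                "phenotype": r.phenotype,
                "gonopore_config": r.gonopore_config,
                "w_band": r.w_band,
                "z_band": r.z_band,
                "genotype": r.genotype.value if r.genotype is not None else None,
                "progeny": r.progeny,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records: Iterable[IndividualRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, na_rep="NA")


def read_cohort_csv(path: str | Path) -> list[IndividualRecord]:
    """Read and validate a cohort CSV.

    Genotypes absent from the file are back-filled from the marker bands
    where the band pattern determines one; every (genotype, phenotype) pair
    is checked for admissibility, with row-level error messages.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True, na_values=["NA"])
    missing_cols = {"id", "phenotype"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing_cols)}")
    records: list[IndividualRecord] = []
    for i, row in df.iterrows():
        def get(col: str) -> Any:
            v = row.get(col)
            return None if (v is None or (isinstance(v, float) and np.isnan(v))) else v

        geno_raw = get("genotype")
        try:
            genotype = Genotype(geno_raw) if geno_raw is not None else None
        except ValueError:
            raise ValueError(
                f"{path}, row {i}: unknown genotype {geno_raw!r}"
            ) from None
        rec = IndividualRecord(
            id=str(row["id"]),
            site=str(get("site") or ""),
            phenotype=str(row["phenotype"]),
            gonopore_config=get("gonopore_config"),
            w_band=_parse_bool(get("w_band"), i, "w_band"),
            z_band=_parse_bool(get("z_band"), i, "z_band"),
            genotype=genotype,
            progeny=get("progeny"),
        )
        resolved = rec.resolve_genotype()
        if rec.genotype is None and resolved is not None:
            rec.genotype = resolved
        if resolved is not None:
            try:
                classify_individual(resolved, rec.phenotype)
            except InadmissiblePairError as e:
                raise ValueError(f"{path}, row {i} (id={rec.id!r}): {e}") from None
        records.append(rec)
    return records


def read_tag_matrix(
    matrix_path: str | Path,
    sex_map_path: str | Path,
    binarize_min: int = 1,
) -> TagMatrix:
    """Read a tags x samples TSV (0/1 or read counts) plus a sample-sex map.

    Missing cells are treated as absent (coded 0) and recorded in the
    matrix's missing mask; counts are binarized at ``binarize_min``.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sex_map = pd.read_csv(sex_map_path, sep="\t", header=None,
                          names=["sample", "sex"], dtype=str, comment="#")
    sex_by_sample = dict(zip(sex_map["sample"], sex_map["sex"]))
    unknown = [s for s in df.columns if s not in sex_by_sample]
    if unknown:
        raise ValueError(f"samples without a sex label: {unknown}")
    missing = df.isna().to_numpy()
    counts = df.fillna(0).to_numpy(dtype=float)
    presence = (counts >= binarize_min).astype(np.int8)
    presence[missing] = 0
    return TagMatrix(
        tags=[str(t) for t in df.index],
        samples=[str(s) for s in df.columns],
        presence=presence,
        sample_sex=[sex_by_sample[s] for s in df.columns],
        missing=missing if missing.any() else None,
    )


def write_tag_matrix(m: TagMatrix, matrix_path: str | Path,
                     sex_map_path: str | Path) -> None:
    m.to_frame().to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample": m.samples, "sex": m.sample_sex}).to_csv(
        sex_map_path, sep="\t", header=False, index=False
    )


def trajectory_to_frame(traj: Trajectory, params: DemographicParams) -> pd.DataFrame:
    """Trajectory as a tidy table: one row per step, abundances, lambda, fractions."""
    rows = []
    for i, s in enumerate(traj.states):
        n = s.total
        rows.append(
            {
                "step": s.t,
                "years": s.t * params.step_months / 12.0,
                "N_ZZ": s.zz, "N_IS": s.is_, "N_WZ": s.wz, "N_WW": s.ww,
                "N_total": n,
                "lambda_t": traj.lambdas[i - 1] if i > 0 else np.nan,
                "frac_ZZ": s.zz / n if n > 0 else np.nan,
                "frac_IS": s.is_ / n if n > 0 else np.nan,
                "frac_WZ": s.wz / n if n > 0 else np.nan,
                "frac_WW": s.ww / n if n > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a JSON or YAML parameter config."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record emitted alongside every pipeline run."""

    subcommand: str
    parameters: dict[str, Any]
    inputs: list[str]
    outputs: list[str]
    seed: int | None
    version: str = __version__
    timestamp: str = dataclasses.field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n",
            encoding="utf-8",
        )


def _state_from_config(d: dict[str, Any]) -> PopulationState:
    return PopulationState(
        zz=float(d.get("ZZ", 0)), is_=float(d.get("IS", 0)),
        wz=float(d.get("WZ", 0)), ww=float(d.get("WW", 0)),
    )


def _params_from_config(cfg: dict[str, Any]) -> DemographicParams:
    return DemographicParams(
        alpha=float(cfg.get("alpha", 0.04)),
        sigma0=float(cfg.get("sigma0", 1.0)),
        sigma_a=float(cfg.get("sigma_a", 0.6)),
        phi=float(cfg.get("phi", 1.2)),
        step_months=float(cfg.get("step_months", 6.0)),
    )


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> RunManifest:
    """Execute the configured stages and write outputs plus a manifest.

    Recognised stage keys in ``config``: ``simulate`` (cross or native
    cohort), ``project`` (trajectory CSV), ``ltsd`` (stable-distribution
    JSON), ``tally`` (cohort summary JSON), ``screen`` (marker screen TSV).
    All randomness flows through the single top-level ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = _params_from_config(config)
    seed = config.get("seed")
    rng = np.random.default_rng(seed)
    outputs: list[str] = []
    inputs: list[str] = []
    records = None

    sim_cfg = config.get("simulate")
    if sim_cfg:
        kind = sim_cfg.get("kind", "native")
        if kind == "cross":
            records = simulate_cross(
                Genotype(sim_cfg.get("sire", "WZ")), Genotype(sim_cfg.get("dam", "WZ")),
                int(sim_cfg.get("n", 100)), alpha=params.alpha,
                genotyping_error=float(sim_cfg.get("genotyping_error", 0.0)), seed=rng,
            )
        elif kind == "native":
            records = simulate_native_population(
                int(sim_cfg.get("n", 1000)), alpha=params.alpha,
                genotyping_error=float(sim_cfg.get("genotyping_error", 0.0)), seed=rng,
            )
        else:
            raise ValueError(f"unknown simulate kind {kind!r}")
        p = out_dir / "cohort.csv"
        write_cohort_csv(records, p)
        outputs.append(str(p))
    elif config.get("cohort"):
        inputs.append(str(config["cohort"]))
        records = read_cohort_csv(config["cohort"])

    if config.get("ltsd"):
        sd = stable_distribution(params.alpha, params)
        p = out_dir / "ltsd.json"
        p.write_text(json.dumps(
            {
                "alpha": params.alpha,
                "percent": {c.value: v for c, v in sd.percentages().items()},
                "lambda_inf": sd.lambda_inf,
                "iterations": sd.n_iterations,
            }, indent=2) + "\n", encoding="utf-8")
        outputs.append(str(p))

    proj_cfg = config.get("project")
    if proj_cfg:
        initial = _state_from_config(proj_cfg.get("initial", {"ZZ": 100, "WZ": 100}))
        traj = simulate_trajectory(
            initial, params, int(proj_cfg.get("n_steps", 60)),
            mode=proj_cfg.get("mode", "deterministic"),
            seed=int(rng.integers(2**31)),
        )
        p = out_dir / "trajectory.csv"
        trajectory_to_frame(traj, params).to_csv(p, index=False, na_rep="NA")
        outputs.append(str(p))

    if config.get("tally"):
        if records is None:
            raise ValueError("tally stage requires a cohort (simulate or cohort path)")
        summary = tally_cohort(records)
        p = out_dir / "tally.json"
        p.write_text(json.dumps(dataclasses.asdict(summary), indent=2) + "\n",
                     encoding="utf-8")
        outputs.append(str(p))

    screen_cfg = config.get("screen")
    if screen_cfg:
        matrix = read_tag_matrix(
            screen_cfg["matrix"], screen_cfg["sex_map"],
            binarize_min=int(screen_cfg.get("binarize_min", 1)),
        )
        inputs += [str(screen_cfg["matrix"]), str(screen_cfg["sex_map"])]
        res = screen_sex_markers(matrix, float(screen_cfg.get("threshold", 0.6)))
        p = out_dir / "screen.tsv"
        res.table.to_csv(p, sep="\t", index=False)
        outputs.append(str(p))

    manifest = RunManifest(
        subcommand="run-pipeline",
        parameters={k: v for k, v in config.items()},
        inputs=inputs,
        outputs=outputs,
        seed=seed,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
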