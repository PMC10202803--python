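"""Patient-table CSV round-tripping, YAML configuration, and pipeline stages.

Patient tables are CSV with the documented header (empty field = absent):

    patient_id, cohort_id, arm, enrollment_week, evaluable,
    best_response_inv, best_response_ind, response_onset_week,
    progression_week, death_week, last_assessment_week,
    new_anticancer_therapy, withdrew_consent, n_post_baseline_assessments

The three trailing assessability columns are optional on read.  Scenario and
design configurations are YAML/JSON mappings mirroring the dataclass fields;
every artifact written by a pipeline stage embeds the seed and a hash of the
configuration that produced it, so results can be regenerated exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .bhm import BHMConfig, CohortData, fit_bhm
from .cohorts import CohortSpec, default_cohort_specs, reported_best_response_counts
from .design import DesignRules, evaluate_interim, operating_characteristics
from .efficacy import derive_endpoint, orr_report, orr_report_from_counts
from .records import PatientRecord
from .response import RULE_REGISTRY, classify_responder
from .simulate import TrialScenario, generate_patients
from .survival import NOT_REACHED, km_fit

__all__ = [
    "RunConfig",
    "read_patients",
    "write_patients",
    "load_scenario",
    "load_design_rules",
    "load_bhm_config",
    "run_pipeline",
    "PatientTableError",
]

log = logging.getLogger("baskettrial")

_COLUMNS = [
    "patient_id",
    "cohort_id",
    "arm",
    "enrollment_week",
    "evaluable",
    "best_response_inv",
    "best_response_ind",
    "response_onset_week",
    "progression_week",
    "death_week",
    "last_assessment_week",
    "new_anticancer_therapy",
    "withdrew_consent",
    "n_post_baseline_assessments",
]
_MANDATORY = _COLUMNS[:11]
_FLOATS = {
    "enrollment_week",
    "response_onset_week",
    "progression_week",
    "death_week",
    "last_assessment_week",
}
_BOOLS = {"evaluable", "new_anticancer_therapy", "withdrew_consent"}


class PatientTableError(ValueError):
    """CSV parsing/validation failure, naming the offending row and column."""


def write_patients(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in records:
            row = []
            for col in _COLUMNS:
                v = getattr(r, col)
                if v is None:
                    row.append("")
                elif isinstance(v, bool):
                    row.append("true" if v else "false")
                elif isinstance(v, float):
                    row.append(repr(v))
                else:
                    row.append(str(v))
            writer.writerow(row)


def _parse_cell(value: str, col: str, rownum: int):
    if value == "":
        if col in ("patient_id", "cohort_id", "arm"):
            raise PatientTableError(f"row {rownum}: mandatory column {col!r} is empty")
        return None
    if col in _FLOATS:
        try:
            return float(value)
        except ValueError:
            raise PatientTableError(
                f"row {rownum}, column {col!r}: unparseable time {value!r}"
            ) from None
    if col in _BOOLS:
        low = value.strip().lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise PatientTableError(
            f"row {rownum}, column {col!r}: unparseable boolean {value!r}"
        )
    if col == "n_post_baseline_assessments":
        try:
            return int(value)
        except ValueError:
            raise PatientTableError(
                f"row {rownum}, column {col!r}: unparseable count {value!r}"
            ) from None
    return value


def read_patients(
    path: Union[str, Path], specs: Optional[Sequence[CohortSpec]] = None
) -> list[PatientRecord]:
    """Read a patient table, validating categories when specs are given.

    Without explicit specs, cohorts present in the default registry are
    validated against their registered vocabulary; unknown cohorts pass
    through unvalidated.
    """
    path = Path(path)
    if specs is None:
        spec_by_id = {s.cohort_id: s for s in default_cohort_specs()}
    else:
        spec_by_id = {s.cohort_id: s for s in specs}
    records: list[PatientRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PatientTableError("empty file: missing header row") from None
        missing = [c for c in _MANDATORY if c not in header]
        if missing:
            raise PatientTableError(f"missing mandatory columns {missing}")
        idx = {c: header.index(c) for c in header}
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            kwargs = {}
            for col in _COLUMNS:
                if col in idx:
                    kwargs[col] = _parse_cell(row[idx[col]], col, rownum)
            for flag in _BOOLS:
                if kwargs.get(flag) is None:
                    kwargs[flag] = False
            if kwargs.get("n_post_baseline_assessments") is None:
                kwargs["n_post_baseline_assessments"] = 0
            cid = kwargs["cohort_id"]
            spec = spec_by_id.get(cid)
            if spec is not None:
                vocab = RULE_REGISTRY[spec.cohort_class].vocabulary
                for col in ("best_response_inv", "best_response_ind"):
                    cat = kwargs.get(col)
                    if cat is not None and cat not in vocab:
                        raise PatientTableError(
                            f"row {rownum}, column {col!r}: unknown category "
                            f"{cat!r} for cohort {cid!r}"
                        )
            records.append(PatientRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------


def _load_mapping(path: Union[str, Path]) -> dict:
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_scenario(path: Union[str, Path]) -> TrialScenario:
    return TrialScenario(**_load_mapping(path))


def load_design_rules(path: Union[str, Path]) -> DesignRules:
    return DesignRules(**_load_mapping(path))


def load_bhm_config(path: Union[str, Path]) -> BHMConfig:
    return BHMConfig(**_load_mapping(path))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

COMMANDS = ("simulate-data", "interim", "oc", "analyze", "fixtures")


@dataclass
class RunConfig:
    """One pipeline invocation: a stage, its inputs, outputs and seed."""

    command: str
    out_dir: Union[str, Path] = "."
    patients_path: Optional[Union[str, Path]] = None
    scenario: Optional[TrialScenario] = None
    design: DesignRules = field(default_factory=DesignRules)
    bhm: BHMConfig = field(default_factory=BHMConfig)
    specs: Optional[Sequence[CohortSpec]] = None
    n_sims: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ValueError(f"command must be one of {COMMANDS}")
        if self.specs is None:
            self.specs = default_cohort_specs()


def _config_hash(config: RunConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, Path):
            return str(obj)
        return obj

    payload = json.dumps(enc(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {
        "metadata": {"seed": config.seed, "config_hash": _config_hash(config)},
        **payload,
    }
    def default(o):
        if o is NOT_REACHED:
            return "NOT_REACHED"
        if hasattr(o, "tolist"):
            return o.tolist()
        return str(o)

    path.write_text(json.dumps(payload, indent=2, default=default))


def run_pipeline(config: RunConfig) -> int:
    """Execute one pipeline stage; returns 0 on success, 1 on failure.

    Artifacts land in ``config.out_dir`` and embed the seed and configuration
    hash.  Failures are logged and reported through the exit status rather
    than raised, mirroring shell-pipeline semantics.
    """
    try:
        return _run(config)
    except Exception:
        log.exception("pipeline stage %s failed", config.command)
        return 1


def _run(config: RunConfig) -> int:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = list(config.specs)
    log.info("stage=%s seed=%d config=%s", config.command, config.seed, _config_hash(config))

    if config.command == "simulate-data":
        if config.scenario is None:
            raise ValueError("simulate-data requires a scenario")
        records = generate_patients(config.scenario, specs, seed=config.seed)
        write_patients(records, out_dir / "patients.csv")
        _write_json(out_dir / "patients.meta.json", {"n_records": len(records)}, config)
        return 0

    if config.command == "interim":
        if config.patients_path is None:
            raise ValueError("interim requires patients_path")
        records = read_patients(config.patients_path, specs)
        spec_by_id = {s.cohort_id: s for s in specs}
        data = []
        for s in specs:
            recs = [
                r
                for r in records
                if r.cohort_id == s.cohort_id and r.arm == "primary" and r.evaluable
            ]
            x = sum(
                classify_responder(r.best_response_inv, s.cohort_class) for r in recs
            )
            data.append(
                CohortData(cohort_id=s.cohort_id, n_evaluable=len(recs), x_responders=x)
            )
        summary = fit_bhm(data, specs, config.bhm)
        decisions = {
            d.cohort_id: dataclasses.asdict(
                evaluate_interim(
                    d.n_evaluable,
                    summary.prob_exceed(d.cohort_id),
                    config.design,
                    cohort_id=d.cohort_id,
                )
            )
            for d in data
        }
        _write_json(
            out_dir / "interim.json",
            {"posterior": summary.to_json_dict(), "decisions": decisions},
            config,
        )
        return 0

    if config.command == "oc":
        if config.scenario is None:
            raise ValueError("oc requires a scenario")
        oc = operating_characteristics(
            config.scenario,
            specs,
            config.design,
            config.bhm,
            n_sims=config.n_sims,
            seed=config.seed,
        )
        _write_json(
            out_dir / "oc.json", {"n_sims": oc.n_sims, "cohorts": oc.cohorts}, config
        )
        return 0

    if config.command == "analyze":
        if config.patients_path is None:
            raise ValueError("analyze requires patients_path")
        records = read_patients(config.patients_path, specs)
        table = orr_report(records, specs)
        table.to_csv(out_dir / "orr_table.csv")
        spec_by_id = {s.cohort_id: s for s in specs}
        km_out: dict[str, dict] = {}
        for s in specs:
            recs = [r for r in records if r.cohort_id == s.cohort_id]
            if not recs:
                continue
            km_out[s.cohort_id] = {}
            for endpoint in ("DoR", "PFS", "OS"):
                tte = derive_endpoint(recs, endpoint, cohort_class=s.cohort_class)
                if not tte:
                    continue
                est = km_fit(tte)
                med, (lo, hi) = est.median, est.median_ci
                km_out[s.cohort_id][endpoint] = {
                    "n": len(tte),
                    "events": int(est.n_event.sum()),
                    "median_weeks": med,
                    "median_ci_weeks": [lo, hi],
                }
        _write_json(out_dir / "km_summary.json", {"endpoints": km_out}, config)
        return 0

    if config.command == "fixtures":
        fixtures = reported_best_response_counts()
        table = orr_report_from_counts(fixtures, specs)
        table.to_csv(out_dir / "reported_orr.csv")
        _write_json(out_dir / "reported_counts.json", {"cohorts": fixtures}, config)
        return 0

    raise AssertionError("unreachable")
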