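"""Run configuration: one YAML file describing a whole analysis.

Sections (all optional except one data source):

```yaml
data:                # either simulate: {...} or bfile/dosages + pheno paths
  simulate: {n_individuals: 400, n_markers: 600, heritability: 0.5, ...}
qc: {min_maf: 0.05, min_call_rate: 0.95, hwe_p: 1.0e-6, max_missing: 0.10}
methods: [gblup, krr]
cv: {folds: 5, repeats: 10, tuner: tpe, budget: 200}
seed: 0
```

Unknown keys anywhere are rejected before any computation.  The global seed
fans out to per-stage seeds by fixed offsets so stages can be re-run in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .evaluate import CVProtocol
from .genotype_io import QCParams
from .simulate import SimConfig

__all__ = ["RunConfig", "load_run_config"]

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"simulate": 0, "cv": 1}

_DATA_KEYS = {"simulate", "bfile", "dosages", "pheno", "trait"}
_QC_KEYS = {"max_missing", "min_maf", "min_call_rate", "hwe_p"}
_CV_KEYS = {"folds", "repeats", "tuner", "budget", "inner_holdout_fraction",
            "n_inner_splits"}
_SIM_KEYS = {"n_individuals", "n_markers", "n_chromosomes", "maf_range", "n_qtl",
             "heritability", "n_reference"}
_TOP_KEYS = {"data", "qc", "methods", "cv", "seed", "out"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    """A validated analysis description: data, QC, methods, CV protocol, seed."""

    sim: SimConfig | None
    bfile: Path | None
    dosages: Path | None
    pheno: Path | None
    trait: str | None
    qc: QCParams
    methods: list[str]
    protocol: CVProtocol
    seed: int
    out: Path = field(default=Path("gptk_out"))


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    seed = int(raw.get("seed", 0))

    data = raw.get("data") or {}
    _check_keys(data, _DATA_KEYS, "data")
    sim = None
    if "simulate" in data:
        simsec = data["simulate"] or {}
        _check_keys(simsec, _SIM_KEYS, "data.simulate")
        if "maf_range" in simsec:
            simsec["maf_range"] = tuple(simsec["maf_range"])
        sim = SimConfig(seed=seed + SEED_OFFSETS["simulate"], **simsec)
    elif not (data.get("bfile") or data.get("dosages")):
        raise ConfigError("data section needs simulate:, bfile: or dosages:")

    qcsec = raw.get("qc") or {}
    _check_keys(qcsec, _QC_KEYS, "qc")
    qc = QCParams(
        max_missing_per_individual=qcsec.get("max_missing", 0.10),
        min_maf=qcsec.get("min_maf", 0.05),
        min_call_rate=qcsec.get("min_call_rate", 0.95),
        hwe_p_threshold=qcsec.get("hwe_p", 1e-6),
    )

    methods = raw.get("methods") or ["gblup"]
    for m in methods:
        if m not in ("gblup", "krr", "svr"):
            raise ConfigError(f"unknown method {m!r} in methods")

    cvsec = raw.get("cv") or {}
    _check_keys(cvsec, _CV_KEYS, "cv")
    protocol = CVProtocol(
        n_folds=cvsec.get("folds", 5),
        n_repeats=cvsec.get("repeats", 10),
        inner_holdout_fraction=cvsec.get("inner_holdout_fraction", 0.2),
        n_inner_splits=cvsec.get("n_inner_splits", 3),
        seed=seed + SEED_OFFSETS["cv"],
        tuner=cvsec.get("tuner", "tpe"),
        budget=cvsec.get("budget", 200),
    )
    return RunConfig(
        sim=sim,
        bfile=Path(data["bfile"]) if data.get("bfile") else None,
        dosages=Path(data["dosages"]) if data.get("dosages") else None,
        pheno=Path(data["pheno"]) if data.get("pheno") else None,
        trait=data.get("trait"),
        qc=qc,
        methods=list(methods),
        protocol=protocol,
        seed=seed,
        out=Path(raw.get("out", "gptk_out")),
    )
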