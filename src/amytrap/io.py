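"""Readers, writers, configuration and the end-to-end pipeline driver.

File conventions: FASTA for protein sequences (via Biopython), long/tidy CSV
for all trace tables with units declared in column names (``_s`` seconds,
``_M`` molar), TSV for scanner matches (1-based inclusive coordinates for
human consumption, BED-style 0-based half-open optionally), JSON for fit
results and manifests, YAML for run configuration.  Writes are atomic
(temp file + rename) and every output directory gets a manifest listing
each artifact with its SHA-256 hash, so reruns can be compared byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from amytrap.sequence_matching import Match, TargetProtein

__all__ = [
    "THT_SCHEMA",
    "BLI_SCHEMA",
    "MDS_SCHEMA",
    "IOValidationError",
    "read_fasta",
    "read_trace_csv",
    "write_results",
    "matches_to_tsv",
    "matches_to_bed",
    "load_config",
    "run_pipeline",
]


class IOValidationError(ValueError):
    pass


# Schema = (required columns, key columns that must be unique together)
THT_SCHEMA = ({"t_s", "F", "binder_conc_M", "replicate"}, ["binder_conc_M", "replicate", "t_s"])
BLI_SCHEMA = (
    {"time_s", "conc_M", "phase", "response"},
    ["conc_M", "phase", "time_s"],
)
MDS_SCHEMA = ({"conc_M", "replicate", "fraction_bound"}, ["conc_M", "replicate"])

_UNIT_SUFFIXES = ("_s", "_M", "_nm")


def read_fasta(path: str | Path) -> list[TargetProtein]:
    """Read protein sequences from FASTA; lowercase letters are uppercased."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise IOValidationError(f"{path}: no FASTA records found")
    return [TargetProtein(rec.id, str(rec.seq).upper()) for rec in records]


def read_trace_csv(path: str | Path, schema) -> pd.DataFrame:
    """Read a tidy trace CSV and validate it against a schema.

    The schema is ``(required_columns, key_columns)``; missing columns,
    non-numeric unit-bearing columns and duplicate key rows produce precise
    errors.
    """
    path = Path(path)
    required, keys = schema
    frame = pd.read_csv(path)
    missing = set(required) - set(frame.columns)
    if missing:
        raise IOValidationError(f"{path}: missing columns {sorted(missing)}")
    for col in frame.columns:
        if col.endswith(_UNIT_SUFFIXES):
            try:
                frame[col] = pd.to_numeric(frame[col])
            except (ValueError, TypeError) as exc:
                raise IOValidationError(
                    f"{path}: column {col!r} declares units but is not numeric: {exc}"
                ) from exc
    if "replicate" in keys and "replicate" in frame.columns:
        dup_keys = keys
    else:
        dup_keys = [k for k in keys if k in frame.columns]
    dups = frame.duplicated(subset=dup_keys)
    if dups.any():
        first = frame.index[dups][0]
        raise IOValidationError(
            f"{path}: duplicate {tuple(dup_keys)} row at line {first + 2}"
        )
    return frame


def _atomic_write(path: Path, payload: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(out_dir: str | Path, objects: Mapping[str, object]) -> dict:
    """Write a mapping of name -> object to ``out_dir`` and return a manifest.

    DataFrames become CSV (``.tsv`` names use tabs), strings are written
    verbatim, everything else is serialized as JSON.  The manifest maps each
    file name to its SHA-256 and is itself written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, obj in objects.items():
        path = out / name
        if isinstance(obj, pd.DataFrame):
            sep = "\t" if name.endswith(".tsv") else ","
            payload = obj.to_csv(index=False, sep=sep).encode()
        elif isinstance(obj, str):
            payload = obj.encode()
        else:
            payload = json.dumps(_jsonable(obj), indent=2, sort_keys=True).encode()
        _atomic_write(path, payload)
        manifest[name] = hashlib.sha256(payload).hexdigest()
    _atomic_write(
        out / "manifest.json",
        json.dumps(manifest, indent=2, sort_keys=True).encode(),
    )
    return manifest


def matches_to_tsv(matches: Iterable[Match]) -> pd.DataFrame:
    """Match table with 1-based inclusive coordinates for reports."""
    return pd.DataFrame(
        [
            {
                "protein": m.protein,
                "start_1based": m.start + 1,
                "end_1based": m.end,
                "window": m.window_seq,
                "template": m.template,
                "buried_residues": m.buried_residues,
                "orientation": m.orientation,
            }
            for m in matches
        ]
    )


def matches_to_bed(matches: Iterable[Match]) -> pd.DataFrame:
    """BED-like intervals (0-based half-open)."""
    return pd.DataFrame(
        [
            {
                "chrom": m.protein,
                "start": m.start,
                "end": m.end,
                "name": f"{m.template}:{m.window_seq}",
            }
            for m in matches
        ]
    )


_KNOWN_CONFIG_KEYS = {
    "seed",
    "out_dir",
    "monomer_conc_M",
    "binder_kd_M",
    "binder_concs_M",
    "k2_factors",
    "noise_sigma",
    "replicates",
    "dt_s",
    "potency_increase",
    "log_level",
}


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise IOValidationError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _KNOWN_CONFIG_KEYS
    if unknown:
        raise IOValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def run_pipeline(config: dict) -> dict:
    """Run the full synthetic workflow: scan -> bind -> aggregate -> infer.

    Stages, all deterministic given ``seed``:

    1. scan the bundled amyloidogenic targets with the default templates;
    2. generate an MDS titration at the configured binder affinity and
       refit the monomer Kd (the "bind" stage);
    3. generate a ThT inhibition dataset, fit the uninhibited rate
       products, fit secondary-nucleation factors on top of the measured
       sequestration, and compute the half-time potency concentration.

    Results are written to ``out_dir`` with a manifest; the manifest and
    headline numbers are returned.
    """
    import logging

    from amytrap import inhibition, sequence_matching, synthetic
    from amytrap.binding_models import fit_mds_quadratic

    log = logging.getLogger("amytrap.pipeline")
    logging.basicConfig(level=getattr(logging, config.get("log_level", "INFO")))

    seed = int(config.get("seed", 0))
    out_dir = config.get("out_dir", "amytrap_run")
    binder_kd = float(config.get("binder_kd_M", 83e-9))
    monomer = float(config.get("monomer_conc_M", 2e-6))
    binder_concs = tuple(config.get("binder_concs_M", (0.0, 0.5e-6, 1e-6)))
    k2_factors = {
        float(k): float(v) for k, v in (config.get("k2_factors") or {}).items()
    }
    noise = float(config.get("noise_sigma", 0.02))
    replicates = int(config.get("replicates", 3))
    dt = float(config.get("dt_s", 165.0))
    increase = float(config.get("potency_increase", 0.5))

    log.info("stage 1/3: burial-pattern scan (seed=%d)", seed)
    matches = []
    for protein in sequence_matching.load_targets():
        for tpl in sequence_matching.default_templates():
            matches.extend(sequence_matching.scan_sequence(tpl, protein))

    log.info("stage 2/3: MDS Kd fit (binder_kd=%.3g M)", binder_kd)
    mds = synthetic.gen_mds_dataset(seed=seed, kd=binder_kd)
    mds_fit = fit_mds_quadratic(mds.data, l_tot=mds.truth["l_tot"])
    kd_hat = mds_fit.params["kd"]

    log.info("stage 3/3: ThT inhibition analysis (monomer=%.3g M)", monomer)
    params = synthetic.default_aggregation_parameters(m_total=monomer)
    tht = synthetic.gen_tht_dataset(
        seed=seed + 1,
        params=params,
        binder_kd=binder_kd,
        binder_concs=binder_concs,
        k2_factors=k2_factors or None,
        replicates=replicates,
        dt=dt,
        noise_sigma=noise,
    )
    if not any(c > 0 for c in binder_concs):
        raise IOValidationError("pipeline needs at least one nonzero binder_conc")
    norm = inhibition.normalize_tht(tht)
    unfit = inhibition.fit_uninhibited(norm)
    seq_only = inhibition.predict_sequestration_only(
        unfit, kd_hat, [c for c in binder_concs if c > 0], dataset=norm
    )
    full = inhibition.fit_secondary_modulation(norm, unfit, binder_kd=kd_hat)
    potency = inhibition.potency_concentration(
        unfit, kd_hat, modulation=full.k2_factors, increase=increase
    )
    full.potency_conc = potency

    results = {
        "seed": seed,
        "mds_kd_M": kd_hat,
        "uninhibited": {
            "kn_kplus": unfit.kn_kplus,
            "k2_kplus": unfit.k2_kplus,
            "half_time_s": unfit.half_time_s,
        },
        "k2_factors": full.k2_factors,
        "sequestration_only_residuals": {
            str(c): d["residual_norm"] for c, d in seq_only.items()
        },
        "modulation_residuals": {str(c): v for c, v in full.residual_norms.items()},
        "half_times_s": {str(c): v for c, v in full.half_times.items()},
        "excluded_concs_M": full.excluded_concs,
        "potency_conc_M": potency if potency is not None else "not reached",
    }
    manifest = write_results(
        out_dir,
        {
            "matches.tsv": matches_to_tsv(matches),
            "tht_data.csv": tht.to_frame(),
            "mds_data.csv": mds.data,
            "results.json": results,
        },
    )
    return {"manifest": manifest, "results": results}
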