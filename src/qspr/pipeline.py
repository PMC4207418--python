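"""End-to-end orchestration: molecules → descriptors → split → model → reports.

A run writes, under its output directory: ``desc.csv`` (descriptor
table), ``split.json`` (train/test/external partition with the exclusion
radius and scaling), ``model.json`` (the fitted GRNN), ``pred.csv``
(per-compound actual/predicted %F with split membership), ``report.json``
(per-split fit statistics), ``corr.csv`` (descriptor correlation matrix)
and ``run.json`` (every parameter and seed). Re-running with the same
configuration reproduces each file bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem_io, descriptors, grnn, metrics, splitting, synthetic_data

logger = logging.getLogger(__name__)

#: the 11 descriptor columns the regression model consumes
MODEL_FEATURES = [
    "nsb", "nab", "yz_shadow", "grav3", "saaa", "n_oxygen", "n_nitrogen",
    "rel_oxygen", "rel_nitrogen", "max_h_charge", "hasa2",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; ``input_path=None`` means synthetic data."""

    output_dir: str
    input_path: str | None = None
    input_format: str | None = None  # smiles | sdf | csv
    target_col: str = "F"
    seed: int = 7
    n_synthetic: int = 217
    probe_radius: float = 1.4
    grid_resolution: float = 0.1
    train_fraction: float = 159 / 209
    n_external: int = 8
    sigma_bounds: tuple[float, float] = (-3.0, 2.0)


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.round(12).to_csv().encode()).hexdigest()


def _build_descriptor_table(config: PipelineConfig) -> pd.DataFrame:
    if config.input_path is None:
        return synthetic_data.simulate_descriptor_table(
            synthetic_data.SyntheticConfig(n=config.n_synthetic, seed=config.seed)
        )
    path = Path(config.input_path)
    fmt = config.input_format or ("csv" if path.suffix == ".csv" else None)
    if fmt == "csv":
        table = chem_io.read_descriptor_table(path)
        if config.target_col not in table.columns:
            raise ValueError(f"target column {config.target_col!r} missing from {path}")
        return table
    mols = chem_io.read_molecules(path, fmt)
    dconf = descriptors.DescriptorConfig(
        probe_radius=config.probe_radius, grid_resolution=config.grid_resolution
    )
    rows = {}
    for m in mols:
        prepared = chem_io.prepare_molecule(m, seed=config.seed)
        vec = descriptors.compute_all(prepared, dconf)
        row = {c: getattr(vec, c) for c in chem_io.DESCRIPTOR_COLUMNS}
        # the model consumes the raw (unnormalised) shadow area
        row["yz_shadow"] = descriptors.shadow_area(prepared, config.grid_resolution)[0]
        rows[m.id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "id"
    return table


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow and return the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = _build_descriptor_table(config)
    if config.target_col not in table.columns:
        raise ValueError(
            f"pipeline stage 'split': target column {config.target_col!r} not in table"
        )
    features = [c for c in MODEL_FEATURES if c in table.columns]
    missing = sorted(set(MODEL_FEATURES) - set(features))
    if missing:
        raise ValueError(f"pipeline stage 'descriptors': missing model columns {missing}")
    table.to_csv(out / "desc.csv", float_format="%.12g")

    split = splitting.split_dataset(
        table[features + [config.target_col]],
        target_col=config.target_col,
        train_fraction=config.train_fraction,
        n_external=config.n_external,
        seed=config.seed,
    )
    (out / "split.json").write_text(json.dumps({
        "train_ids": list(split.train_ids),
        "test_ids": list(split.test_ids),
        "external_ids": list(split.external_ids),
        "radius": split.radius,
        "scaling": {
            "columns": list(split.scaling.columns),
            "mean": split.scaling.mean.tolist(),
            "sd": split.scaling.sd.tolist(),
        },
    }, indent=2))

    train = table.loc[list(split.train_ids)]
    test = table.loc[list(split.test_ids)]
    external = table.loc[list(split.external_ids)]
    external_before = _checksum(external)

    model, trace = grnn.fit_grnn(
        train, test, target_col=config.target_col, feature_cols=features,
        log_sigma_bounds=config.sigma_bounds,
    )
    save_grnn(model, trace, out / "model.json")

    preds = []
    reports = []
    for name, part in (("train", train), ("test", test), ("external", external)):
        batch = grnn.grnn_predict_batch(model, part, target_col=config.target_col)
        batch["split"] = name
        preds.append(batch)
        reports.append(metrics.evaluate(batch["actual"].to_numpy(),
                                        batch["predicted"].to_numpy(), name).to_dict())
    pred = pd.concat(preds)
    pred.index.name = "id"
    pred.to_csv(out / "pred.csv", float_format="%.12g")
    (out / "report.json").write_text(json.dumps(reports, indent=2))

    corr = metrics.correlation_matrix(table, columns=features)
    corr.to_frame().to_csv(out / "corr.csv", float_format="%.12g")

    # leakage guard: fitting must not have touched the external rows
    assert _checksum(table.loc[list(split.external_ids)]) == external_before

    (out / "run.json").write_text(json.dumps({
        "config": asdict(config),
        "n_compounds": len(table),
        "split_sizes": {
            "train": len(split.train_ids),
            "test": len(split.test_ids),
            "external": len(split.external_ids),
        },
        "sigma": model.sigma,
        "desc_checksum": _checksum(table),
    }, indent=2))
    logger.info("pipeline run complete: %s", out)
    return out


def save_grnn(model: grnn.GRNNModel, trace: grnn.SelectionTrace, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "sigma": model.sigma,
        "clip": model.clip,
        "train_X": model.train_X.tolist(),
        "train_y": model.train_y.tolist(),
        "scaling": {
            "columns": list(model.scaling.columns),
            "mean": model.scaling.mean.tolist(),
            "sd": model.scaling.sd.tolist(),
        },
        "trace": {"sigma": trace.sigma, "train_rmse": trace.train_rmse,
                  "test_rmse": trace.test_rmse},
    }, indent=2))


def load_grnn(path: str | Path) -> grnn.GRNNModel:
    blob = json.loads(Path(path).read_text())
    scaling = splitting.Scaling(
        columns=tuple(blob["scaling"]["columns"]),
        mean=np.array(blob["scaling"]["mean"]),
        sd=np.array(blob["scaling"]["sd"]),
    )
    return grnn.GRNNModel(
        train_X=np.array(blob["train_X"]),
        train_y=np.array(blob["train_y"]),
        sigma=blob["sigma"],
        scaling=scaling,
        clip=blob["clip"],
    )
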