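"""End-to-end experiment driver.

Reproduces the three studies at configurable scale:

1. train/test on a dataset simulated and reconstructed with one fixed PSF;
2. apply the experiment-1 network to data generated with per-case PSFs
   drawn from N(4.5, 0.2^2) mm (axial = transaxial / 1.125);
3. apply the experiment-1 network to hollow tumours (> 5 ml) simulated at
   half and at twice the nominal prompt count.

Every case is generated from a seed fanned out from the master seed, so a
run is reproducible end to end.  The ``full`` preset records the full-protocol settings
(344 x 344 x 127 grid, 100M prompts, 2110 cases, 500 epochs); the ``desk``
preset keeps the same pipeline at workstation scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnn, osem, phantom, projector, quantify

__all__ = [
    "ExperimentConfig",
    "SimulatedCase",
    "ExperimentResult",
    "full_scale",
    "desk_scale",
    "generate_case",
    "build_dataset",
    "split_dataset",
    "evaluate_cases",
    "run_experiment",
]

_PATTERNS = ("uniform", "halves", "hollow")


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved settings of one experiment run."""

    experiment: int = 1
    preset: str = "desk"
    composition: dict = field(
        default_factory=lambda: {"uniform": 20, "halves": 20, "hollow": 20}
    )
    grid_shape: tuple[int, int, int] = (96, 96, 48)
    voxel_size: tuple[float, float, float] = (2.09, 2.09, 2.03)
    n_angles: int = 84
    total_prompts: float = 2e6
    trues_fraction: float = projector.DEFAULT_TRUES_FRACTION
    psf_mode: str = "fixed"  # "fixed" | "sampled"
    psf_fwhm_transaxial: float = 4.5
    n_iterations: int = 6
    n_subsets: int = 21
    crop_shape: tuple[int, int, int] = (32, 32, 32)
    epochs: int = 30
    batch_size: int = 4
    learning_rate: float = 0.001
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    augment: bool = True
    augment_factor_range: tuple[float, float] = (0.5, 0.8)
    activity_range: tuple[float, float] = phantom.TUMOUR_ACTIVITY_RANGE
    halves_ratio_range: tuple[float, float] = (1.2, 3.0)
    elongation_max: float = 0.5
    small_volume_range: tuple[float, float] = (0.8, 5.0)
    large_volume_range: tuple[float, float] = (5.0, 8.0)
    large_fraction: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3):
            raise ValueError("experiment must be 1, 2 or 3")
        if self.psf_mode not in ("fixed", "sampled"):
            raise ValueError("psf_mode must be 'fixed' or 'sampled'")
        for pattern, count in self.composition.items():
            if pattern not in _PATTERNS:
                raise ValueError(f"unknown tumour pattern {pattern!r} in composition")
            if int(count) < 0:
                raise ValueError("composition counts must be non-negative")
        if self.n_angles % self.n_subsets != 0:
            raise ValueError("subset count must divide the number of angles")

    @property
    def n_cases(self) -> int:
        return int(sum(self.composition.values()))

    @property
    def grid(self) -> phantom.VoxelGrid:
        return phantom.VoxelGrid(self.grid_shape, self.voxel_size)

    @property
    def recon_config(self) -> osem.ReconConfig:
        return osem.ReconConfig(n_iterations=self.n_iterations, n_subsets=self.n_subsets)


def full_scale(experiment: int = 1) -> ExperimentConfig:
    """Full-protocol settings (GPU/cluster scale)."""
    base = dict(
        preset="full",
        grid_shape=(344, 344, 127),
        voxel_size=(2.09, 2.09, 2.03),
        n_angles=168,
        total_prompts=1e8,
        crop_shape=(50, 50, 50),
        epochs=500,
        batch_size=50,
        small_volume_range=(0.01, 5.0),
        large_volume_range=(5.0, 200.0),
    )
    if experiment == 1:
        return ExperimentConfig(
            experiment=1,
            composition={"uniform": 800, "halves": 721, "hollow": 589},
            psf_mode="fixed",
            **base,
        )
    if experiment == 2:
        return ExperimentConfig(
            experiment=2,
            composition={"uniform": 33, "halves": 34, "hollow": 33},
            psf_mode="sampled",
            **base,
        )
    return ExperimentConfig(
        experiment=3,
        composition={"hollow": 10},
        psf_mode="fixed",
        **base,
    )


def desk_scale(experiment: int = 1) -> ExperimentConfig:
    """Workstation-scale settings with the same pipeline."""
    cfg = ExperimentConfig(experiment=experiment)
    if experiment == 2:
        cfg = replace(cfg, composition={"uniform": 5, "halves": 5, "hollow": 5},
                      psf_mode="sampled")
    elif experiment == 3:
        cfg = replace(cfg, composition={"hollow": 4})
    return cfg


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCase:
    """Everything produced for one tumour: ground truth, raw data, recon, crops."""

    case_id: str
    spec: phantom.TumourSpec
    record: phantom.TumourRecord
    psf: projector.PSFSpec
    total_prompts: float
    seeds: dict
    truth: phantom.ActivityVolume
    recon: phantom.ActivityVolume
    training_case: cnn.TrainingCase


def _draw_spec(cfg: ExperimentConfig, pattern: str, rng: np.random.Generator) -> phantom.TumourSpec:
    a_lo, a_hi = cfg.activity_range
    primary = float(rng.uniform(a_lo, a_hi))
    secondary = None
    if pattern == "halves":
        ratio = float(rng.uniform(*cfg.halves_ratio_range))
        secondary = primary / ratio
    if rng.random() < cfg.large_fraction:
        v_lo, v_hi = cfg.large_volume_range
    else:
        v_lo, v_hi = cfg.small_volume_range
    volume = float(np.exp(rng.uniform(math.log(v_lo), math.log(v_hi))))
    return phantom.TumourSpec(
        pattern=pattern,
        target_volume_ml=volume,
        primary_activity=primary,
        secondary_activity=secondary,
        elongation=float(rng.uniform(0.0, cfg.elongation_max)),
        seed=int(rng.integers(2**31)),
    )


def generate_case(
    cfg: ExperimentConfig,
    spec: phantom.TumourSpec,
    case_seed: int,
    case_id: str,
    torso: phantom.TorsoPhantom | None = None,
    psf: projector.PSFSpec | None = None,
    total_prompts: float | None = None,
) -> SimulatedCase:
    """Simulate, reconstruct and crop one tumour case."""
    grid = cfg.grid
    rng = np.random.default_rng(case_seed)
    seeds = {
        "case": int(case_seed),
        "placement": int(rng.integers(2**31)),
        "noise": int(rng.integers(2**31)),
        "psf": int(rng.integers(2**31)),
    }
    if torso is None:
        torso = phantom.make_torso_phantom(grid)
    if psf is None:
        if cfg.psf_mode == "sampled":
            psf = projector.sample_psf_dataset2(np.random.default_rng(seeds["psf"]))
        else:
            psf = projector.PSFSpec.from_transaxial(cfg.psf_fwhm_transaxial)
    prompts_target = cfg.total_prompts if total_prompts is None else total_prompts

    mask = phantom.sample_tumour_shape(spec, grid)
    truth, record = phantom.assemble_ground_truth(torso, mask, spec, seeds["placement"])

    # the tumour displaces lung tissue: give it soft-tissue attenuation
    mu_values = torso.attenuation.values.copy()
    mu_values[record.mask] = torso.organ_table["soft_tissue"][1]
    mu = phantom.AttenuationVolume(grid, mu_values)

    geometry = projector.default_geometry(grid, n_angles=cfg.n_angles)
    att = projector.attenuation_factors(mu, geometry)
    blurred = phantom.ActivityVolume(
        grid, projector.apply_image_psf(truth.values, psf, grid.voxel_size)
    )
    trues = projector.forward_project(blurred, None, geometry, att=att)
    acq = projector.AcquisitionSpec(
        total_prompts=prompts_target,
        trues_fraction=cfg.trues_fraction,
        psf=psf,
        noise_seed=seeds["noise"],
    )
    contaminated = projector.scale_and_contaminate(trues, acq)
    counts = projector.poisson_sample(contaminated.expected, seeds["noise"])

    recon_cfg = replace(cfg.recon_config, psf=psf)
    recon = osem.osem_reconstruct(
        counts, mu, contaminated.background, recon_cfg,
        trues_scale=contaminated.trues_scale, att=att,
    )

    truth_crop, offset = phantom.crop_around_tumour(truth.values, record.centroid, cfg.crop_shape)
    recon_crop, _ = phantom.crop_around_tumour(recon.values, record.centroid, cfg.crop_shape)
    mask_crop, _ = phantom.crop_around_tumour(record.mask, record.centroid, cfg.crop_shape)
    meta = {
        "offset": offset,
        "background": record.background_activity,
        "sphericity": record.sphericity,
        "psf": (psf.fwhm_transaxial, psf.fwhm_axial),
        "total_prompts": prompts_target,
    }
    if record.half_masks is not None:
        meta["half_masks_crop"] = tuple(
            phantom.crop_around_tumour(m, record.centroid, cfg.crop_shape)[0]
            for m in record.half_masks
        )
    training_case = cnn.TrainingCase(
        case_id=case_id,
        pattern=spec.pattern,
        recon_crop=recon_crop,
        truth_crop=truth_crop,
        mask_crop=mask_crop,
        volume_ml=record.volume_ml,
        voxel_size=grid.voxel_size,
        meta=meta,
    )
    return SimulatedCase(
        case_id=case_id,
        spec=spec,
        record=record,
        psf=psf,
        total_prompts=prompts_target,
        seeds=seeds,
        truth=truth,
        recon=recon,
        training_case=training_case,
    )


def build_dataset(
    cfg: ExperimentConfig,
    master_seed: int | None = None,
    total_prompts: float | None = None,
) -> list[SimulatedCase]:
    """Generate the full case list of an experiment, deterministically."""
    seed = cfg.master_seed if master_seed is None else master_seed
    rng = np.random.default_rng(seed)
    torso = phantom.make_torso_phantom(cfg.grid)
    cases = []
    i = 0
    for pattern in _PATTERNS:
        for _ in range(int(cfg.composition.get(pattern, 0))):
            spec = _draw_spec(cfg, pattern, rng)
            if cfg.experiment == 3:
                # hollow tumours above 5 ml only
                v_lo, v_hi = cfg.large_volume_range
                spec = replace(
                    spec,
                    target_volume_ml=float(
                        np.exp(rng.uniform(math.log(max(v_lo, 5.0)), math.log(v_hi)))
                    ),
                )
            case_seed = int(rng.integers(2**31))
            cases.append(generate_case(
                cfg, spec, case_seed, case_id=f"exp{cfg.experiment}-{i:04d}",
                torso=torso, total_prompts=total_prompts,
            ))
            i += 1
    return cases


def split_dataset(
    cases: list[SimulatedCase], test_fraction: float, seed: int
) -> tuple[list[SimulatedCase], list[SimulatedCase]]:
    """Shuffled train/test split; the test side is never augmented."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    n_test = int(round(test_fraction * len(cases)))
    test_idx = set(order[:n_test].tolist())
    train = [c for i, c in enumerate(cases) if i not in test_idx]
    test = [c for i, c in enumerate(cases) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# training data preparation
# ---------------------------------------------------------------------------

def normalise_pair(tc: cnn.TrainingCase) -> tuple[np.ndarray, np.ndarray, cnn.NormalizationRecord]:
    """Scale input and target with the reconstructed crop's min/max."""
    x, rec = cnn.minmax_normalize(tc.recon_crop)
    t = (tc.truth_crop - rec.vmin) / rec.scale
    return x.astype(np.float32), t.astype(np.float32), rec


def prepare_training_arrays(
    train_cases: list[cnn.TrainingCase],
) -> tuple[np.ndarray, np.ndarray]:
    xs, ts = [], []
    for tc in train_cases:
        x, t, _ = normalise_pair(tc)
        xs.append(x)
        ts.append(t)
    return np.stack(xs), np.stack(ts)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_cases(
    model: cnn.CNN3D | None,
    cases: list[SimulatedCase],
) -> pd.DataFrame:
    """Per-tumour metrics of the reconstruction and (optionally) the CNN.

    Returns a tidy frame with one row per (case, image) where image is
    ``recon`` or ``pred``.
    """
    rows = []
    for case in cases:
        tc = case.training_case
        images = {"recon": tc.recon_crop}
        if model is not None:
            images["pred"] = cnn.restore_crop(model, tc.recon_crop)
        for name, img in images.items():
            rc = quantify.rc_metrics(
                img, tc.truth_crop, tc.mask_crop, tc.voxel_size, pattern=tc.pattern
            )
            row = {
                "case_id": case.case_id,
                "image": name,
                "pattern": tc.pattern,
                "volume_ml": tc.volume_ml,
                "sphericity": tc.meta["sphericity"],
                "rc_max": rc.rc_max,
                "rc_median": rc.rc_median,
                "rc_peak": rc.rc_peak,
                "mssim": quantify.mssim(img, tc.truth_crop),
                "detected": quantify.detect_tumour(
                    img, tc.mask_crop, tc.meta["background"]
                ),
            }
            if "half_masks_crop" in tc.meta:
                pred_ratio, true_ratio, under = quantify.halves_ratio_analysis(
                    img, tc.truth_crop, tc.meta["half_masks_crop"]
                )
                row.update(
                    half_ratio_pred=pred_ratio,
                    half_ratio_true=true_ratio,
                    half_ratio_underestimated=under,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _metrics_from_frame(df: pd.DataFrame) -> list[quantify.TumourMetrics]:
    out = []
    for _, r in df.iterrows():
        out.append(quantify.TumourMetrics(
            rc_max=r.rc_max,
            rc_peak=r.rc_peak,
            rc_median=None if pd.isna(r.rc_median) else float(r.rc_median),
            mssim=r.mssim,
            volume_ml=r.volume_ml,
            sphericity=r.sphericity,
            pattern=r.pattern,
            detected=bool(r.detected),
        ))
    return out


def summary_tables(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cohort RC tables (volume >= 5 ml and 1-2 ml bins) per image type."""
    tables = {}
    for name, sub in df.groupby("image"):
        reports = _metrics_from_frame(sub)
        try:
            tables[f"{name}_large"] = quantify.binned_rc_summary(reports, "large")
        except ValueError:
            pass
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tables[f"{name}_small"] = quantify.binned_rc_summary(reports, "small")
        except ValueError:
            pass
    return tables


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    config: ExperimentConfig
    metrics: pd.DataFrame
    tables: dict
    manifest: pd.DataFrame
    model: cnn.CNN3D | None = None
    history: dict | None = None
    extra: dict = field(default_factory=dict)


def _manifest_rows(cases: list[SimulatedCase], split: dict | None = None) -> list[dict]:
    rows = []
    for case in cases:
        rows.append({
            "case_id": case.case_id,
            "pattern": case.spec.pattern,
            "volume_ml": case.record.volume_ml,
            "sphericity": case.record.sphericity,
            "primary_activity": case.spec.primary_activity,
            "secondary_activity": case.spec.secondary_activity,
            "background_activity": case.record.background_activity,
            "psf_transaxial_mm": case.psf.fwhm_transaxial,
            "psf_axial_mm": case.psf.fwhm_axial,
            "total_prompts": case.total_prompts,
            "seed": case.seeds["case"],
            "noise_seed": case.seeds["noise"],
            "centroid": json.dumps([round(c, 2) for c in case.record.centroid]),
            "split": (split or {}).get(case.case_id, ""),
        })
    return rows


def run_experiment(
    cfg: ExperimentConfig,
    outdir=None,
    model_path=None,
) -> ExperimentResult:
    """Run one experiment end to end and (optionally) write its artifacts.

    Experiment 1 trains the network; experiments 2 and 3 require the
    experiment-1 checkpoint via ``model_path``.
    """
    if cfg.experiment in (2, 3) and model_path is None:
        raise ValueError(f"experiment {cfg.experiment} needs the experiment-1 checkpoint")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))

    rng = np.random.default_rng(cfg.master_seed)

    if cfg.experiment == 3:
        low = build_dataset(cfg, total_prompts=cfg.total_prompts * 0.5)
        high = build_dataset(cfg, total_prompts=cfg.total_prompts * 2.0)
        model = cnn.CNN3D.load(model_path)
        df_low = evaluate_cases(model, low)
        df_high = evaluate_cases(model, high)
        df_low["prompts_level"] = "low"
        df_high["prompts_level"] = "high"
        df = pd.concat([df_low, df_high], ignore_index=True)
        tables = {
            f"{level}_{k}": t
            for level, d in (("low", df_low), ("high", df_high))
            for k, t in summary_tables(d).items()
        }
        manifest = pd.DataFrame(_manifest_rows(low) + _manifest_rows(high))
        result = ExperimentResult(cfg, df, tables, manifest, model=model)
    elif cfg.experiment == 2:
        cases = build_dataset(cfg)
        model = cnn.CNN3D.load(model_path)
        df = evaluate_cases(model, cases)
        result = ExperimentResult(
            cfg, df, summary_tables(df), pd.DataFrame(_manifest_rows(cases)), model=model
        )
    else:
        cases = build_dataset(cfg)
        train_cases, test_cases = split_dataset(
            cases, cfg.test_fraction, int(rng.integers(2**31))
        )
        tcs = [c.training_case for c in train_cases]
        if cfg.augment:
            # balance the three pattern classes by shrinking large tumours
            tcs = tcs + cnn.balance_classes(
                tcs, factor_range=cfg.augment_factor_range,
                rng=np.random.default_rng(int(rng.integers(2**31))),
            )
        x, t = prepare_training_arrays(tcs)
        model = cnn.build_model(seed=int(rng.integers(2**31)))
        history = cnn.train(model, x, t, cnn.TrainConfig(
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, val_fraction=cfg.val_fraction,
            seed=int(rng.integers(2**31)),
        ))
        df = evaluate_cases(model, test_cases)
        split = {c.case_id: "train" for c in train_cases}
        split.update({c.case_id: "test" for c in test_cases})
        manifest = pd.DataFrame(_manifest_rows(cases, split))
        result = ExperimentResult(
            cfg, df, summary_tables(df), manifest, model=model, history=history,
            extra={"test_cases": test_cases},
        )

    if outdir is not None:
        result.metrics.to_csv(outdir / "metrics.csv", index=False)
        result.manifest.to_csv(outdir / "manifest.csv", index=False)
        for name, table in result.tables.items():
            table.to_csv(outdir / f"table_{name}.csv")
        if result.history is not None:
            pd.DataFrame(result.history).to_csv(outdir / "history.csv", index=False)
        if cfg.experiment == 1 and result.model is not None:
            result.model.save(outdir / "model.npz")
    return result
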