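"""End-to-end study orchestration.

Runs the whole calibration exercise on simulated (or loaded) two-block
spectra: intensity conversion, replicate averaging, MIR truncation, the
six-pretreatment single-block PLS ladder with 8-fold cross-validation,
VIP-based variable reduction and refit, and the three fusion strategies
(mid-level score fusion, SO-PLS with its Måge grid, SO-CovSel), emitting a
consolidated tidy report.

The train/test partition comes from per-block PCA (5 components each),
score concatenation, and a Duplex split (23 train / 10 test for the
33-sample design). All training-time statistics — fold centering, VIP
selection, complexity choices — are computed on the training samples only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as _design
from . import multiblock as _mb
from . import pls as _pls
from . import preprocess as _pre
from . import simulate as _sim
from . import split as _split

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_study", "report_to_csv", "prediction_tables"]

MIR_CUT = 3541.0  # cm^-1; the high-wavenumber MIR side is mostly baseline


@dataclass
class RunConfig:
    """Settings of one full study run."""

    seed: int = 0
    pca_components_per_block: int = 5
    n_test: int = 10
    cv_folds: int = 8
    max_lv_single: int = 15
    max_lv_sopls: int = 12
    max_var_socovsel: int = 6
    vip_threshold: float = 1.0
    mir_cut: float = MIR_CUT
    first_block: str = "NIR"  # first input block of the sequential models
    pretreatments: tuple = tuple(_pre.PRETREATMENTS)
    mir_csv: str | None = None  # load blocks instead of simulating
    nir_csv: str | None = None
    split_json: str | None = None  # reuse a frozen SplitResult


@dataclass
class RunReport:
    config: RunConfig
    rows: list[dict]
    train_ids: list[str]
    test_ids: list[str]
    best_single: dict  # block label -> row label of the winning model
    sopls_lv_pair: tuple[int, int]
    sopls_order_report: dict
    socovsel_selection: dict
    vip_counts: dict  # block -> (kept, total)
    predictions: dict = field(default_factory=dict)  # label -> DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _prepare_block(block: _sim.SpectralBlock, design: pd.DataFrame, cut: float | None):
    """Convert to absorbance, average replicates, optionally truncate."""
    absb = _pre.to_absorbance(block)
    avg = _pre.average_replicates(absb, sample_order=list(design["sample_id"]))
    if cut is not None:
        avg = _pre.truncate(avg, cut)
    return avg


def _pretreat(label: str, matrix: np.ndarray) -> np.ndarray:
    """Apply a named pretreatment without its trailing mean-center (the
    models re-center fold-wise)."""
    spec = _pre.PRETREATMENTS[label].without_centering()
    return _pre.apply_pretreatment(spec, matrix)


def run_study(config: RunConfig) -> RunReport:
    """Execute the full study; deterministic under a fixed seed."""
    design = _design.load_design()
    y_all = _design.recomputed_ee(design)

    logger.info("stage: blocks (seed=%d)", config.seed)
    if config.mir_csv or config.nir_csv:
        if not (config.mir_csv and config.nir_csv):
            raise ValueError("provide both block CSVs or neither")
        mir_raw = _sim.read_block_csv(config.mir_csv)
        nir_raw = _sim.read_block_csv(config.nir_csv)
    else:
        mir_raw = _sim.simulate_block(design, "MIR", _sim.default_profile("MIR", config.seed))
        nir_raw = _sim.simulate_block(design, "NIR", _sim.default_profile("NIR", config.seed))

    mir = _prepare_block(mir_raw, design, config.mir_cut)
    nir = _prepare_block(nir_raw, design, None)
    blocks = {"MIR": mir, "NIR": nir}

    logger.info("stage: split (PCA %d per block, Duplex n_test=%d)",
                config.pca_components_per_block, config.n_test)
    t_conc = _split.concat_scores(
        *(_split.pca_scores(b.matrix, config.pca_components_per_block) for b in blocks.values())
    )
    if config.split_json:
        import json

        frozen = json.loads(Path(config.split_json).read_text())
        split = _split.SplitResult(
            train_ids=frozen["train_ids"],
            test_ids=frozen["test_ids"],
            score_matrix_used=t_conc,
        )
    else:
        split = _split.duplex_split(t_conc, config.n_test, sample_ids=list(design["sample_id"]))
    split.pca_components_per_block = config.pca_components_per_block
    id_index = {sid: i for i, sid in enumerate(design["sample_id"])}
    tr = np.array([id_index[s] for s in split.train_ids])
    te = np.array([id_index[s] for s in split.test_ids])
    y_tr, y_te = y_all[tr], y_all[te]
    fold_assignment = _pls.venetian_folds(y_tr, config.cv_folds)

    rows: list[dict] = []
    predictions: dict[str, pd.DataFrame] = {}
    best_single: dict[str, dict] = {}

    def add_prediction(label, y_true_tr, yhat_tr, y_true_te, yhat_te):
        predictions[label] = pd.DataFrame(
            {
                "sample_id": list(split.train_ids) + list(split.test_ids),
                "set": ["train"] * len(tr) + ["test"] * len(te),
                "ee_true": np.concatenate([y_true_tr, y_true_te]),
                "ee_pred": np.concatenate([yhat_tr, yhat_te]),
            }
        )

    logger.info("stage: single-block ladder (%d pretreatments x 2 blocks)",
                len(config.pretreatments))
    pretreated: dict[tuple[str, str], np.ndarray] = {}
    for block_name, block in blocks.items():
        per_label = []
        for label in config.pretreatments:
            mat = _pretreat(label, block.matrix)
            pretreated[(block_name, label)] = mat
            cv = _pls.cross_validate(
                mat[tr], y_tr, max_lv=config.max_lv_single, fold_assignment=fold_assignment
            )
            per_label.append((label, cv))
        # winner: lowest RMSECV at the chosen complexity
        best_label, best_cv = min(per_label, key=lambda lc: lc[1].rmsecv_per_lv[lc[1].chosen_lv - 1])
        for label, cv in per_label:
            row = {
                "model": f"{block_name} / {label}",
                "blocks": block_name,
                "preprocessing": label,
                "variables": pretreated[(block_name, label)].shape[1],
                "complexity": cv.chosen_lv,
                "rmsecv": float(cv.rmsecv_per_lv[cv.chosen_lv - 1]),
                "rmsep": np.nan,
                "bias_p": np.nan,
                "r2_p": np.nan,
                "selected": label == best_label,
            }
            if label == best_label:
                mat = pretreated[(block_name, label)]
                model = _pls.fit_pls1(mat[tr], y_tr, cv.chosen_lv)
                yhat_te = _pls.predict(model, mat[te])
                rmse, bias, r2 = _pls.metrics(y_te, yhat_te)
                row.update(rmsep=rmse, bias_p=bias, r2_p=r2)
                add_prediction(row["model"], y_tr, _pls.predict(model, mat[tr]), y_te, yhat_te)
                best_single[block_name] = {"label": best_label, "cv": cv, "model": model}
            rows.append(row)

    logger.info("stage: VIP reduction and refit (threshold %.2f)", config.vip_threshold)
    vip_counts: dict[str, tuple[int, int]] = {}
    reduced: dict[str, dict] = {}
    for block_name, info in best_single.items():
        mat = pretreated[(block_name, info["label"])]
        scores = _pls.vip(info["model"])
        _, kept = _pls.select_by_vip(mat[tr], scores, config.vip_threshold)
        vip_counts[block_name] = (int(kept.size), mat.shape[1])
        mat_red = mat[:, kept]
        cv = _pls.cross_validate(
            mat_red[tr], y_tr, max_lv=config.max_lv_single, fold_assignment=fold_assignment
        )
        model = _pls.fit_pls1(mat_red[tr], y_tr, cv.chosen_lv)
        yhat_te = _pls.predict(model, mat_red[te])
        rmse, bias, r2 = _pls.metrics(y_te, yhat_te)
        label = f"{block_name} / {info['label']} + VIP>{config.vip_threshold:g}"
        rows.append(
            {
                "model": label,
                "blocks": block_name,
                "preprocessing": f"{info['label']} + VIP",
                "variables": int(kept.size),
                "complexity": cv.chosen_lv,
                "rmsecv": float(cv.rmsecv_per_lv[cv.chosen_lv - 1]),
                "rmsep": rmse,
                "bias_p": bias,
                "r2_p": r2,
                "selected": True,
            }
        )
        add_prediction(label, y_tr, _pls.predict(model, mat_red[tr]), y_te, yhat_te)
        reduced[block_name] = {"matrix": mat_red, "model": model, "kept": kept, "cv": cv}

    first = config.first_block
    second = "MIR" if first == "NIR" else "NIR"
    X_first, X_second = reduced[first]["matrix"], reduced[second]["matrix"]

    logger.info("stage: mid-level fusion")
    mfirst, msecond = reduced[first]["model"], reduced[second]["model"]
    sc_first_tr = (X_first[tr] - mfirst.x_mean) @ mfirst.weights
    sc_second_tr = (X_second[tr] - msecond.x_mean) @ msecond.weights
    sc_first_te = (X_first[te] - mfirst.x_mean) @ mfirst.weights
    sc_second_te = (X_second[te] - msecond.x_mean) @ msecond.weights
    fusion_model, fusion_cv, yhat_te = _mb.midlevel_fusion(
        sc_first_tr, sc_second_tr, y_tr, sc_first_te, sc_second_te, folds=config.cv_folds
    )
    rmse, bias, r2 = _pls.metrics(y_te, yhat_te)
    rows.append(
        {
            "model": "Mid-level fusion",
            "blocks": f"{first}+{second}",
            "preprocessing": "block scores",
            "variables": sc_first_tr.shape[1] + sc_second_tr.shape[1],
            "complexity": fusion_cv.chosen_lv,
            "rmsecv": float(fusion_cv.rmsecv_per_lv[fusion_cv.chosen_lv - 1]),
            "rmsep": rmse,
            "bias_p": bias,
            "r2_p": r2,
            "selected": True,
        }
    )
    add_prediction(
        "Mid-level fusion",
        y_tr,
        _pls.predict(fusion_model, np.hstack([sc_first_tr, sc_second_tr])),
        y_te,
        yhat_te,
    )

    logger.info("stage: SO-PLS (max %d LV per block)", config.max_lv_sopls)
    grid = _mb.sopls_select(
        X_first[tr], X_second[tr], y_tr,
        max_lv_per_block=config.max_lv_sopls, fold_assignment=fold_assignment,
    )
    sopls_model = _mb.sopls_fit(X_first[tr], X_second[tr], y_tr, *grid.chosen_pair)
    yhat_te = _mb.sopls_predict(sopls_model, X_first[te], X_second[te])
    rmse, bias, r2 = _pls.metrics(y_te, yhat_te)
    rows.append(
        {
            "model": f"SO-PLS ({first}->{second})",
            "blocks": f"{first}+{second}",
            "preprocessing": "VIP-reduced blocks",
            "variables": X_first.shape[1] + X_second.shape[1],
            "complexity": sum(grid.chosen_pair),
            "rmsecv": float(grid.rmsecv[grid.chosen_pair]),
            "rmsep": rmse,
            "bias_p": bias,
            "r2_p": r2,
            "selected": True,
        }
    )
    add_prediction(
        f"SO-PLS ({first}->{second})",
        y_tr,
        _mb.sopls_predict(sopls_model, X_first[tr], X_second[tr]),
        y_te,
        yhat_te,
    )
    order_report = _mb.sopls_order_check(
        X_first[tr], X_second[tr], y_tr, X_first[te], X_second[te], y_te,
        max_lv_per_block=config.max_lv_sopls, folds=config.cv_folds,
    )

    logger.info("stage: SO-CovSel (max %d variables per block)", config.max_var_socovsel)
    cs_grid = _mb.socovsel_select(
        X_first[tr], X_second[tr], y_tr,
        max_var_per_block=config.max_var_socovsel, fold_assignment=fold_assignment,
    )
    cs_model = _mb.socovsel_fit(X_first[tr], X_second[tr], y_tr, *cs_grid.chosen_pair)
    yhat_te = _mb.socovsel_predict(cs_model, X_first[te], X_second[te])
    rmse, bias, r2 = _pls.metrics(y_te, yhat_te)
    rows.append(
        {
            "model": f"SO-CovSel ({first}->{second})",
            "blocks": f"{first}+{second}",
            "preprocessing": "VIP-reduced blocks",
            "variables": sum(cs_grid.chosen_pair),
            "complexity": sum(cs_grid.chosen_pair),
            "rmsecv": float(cs_grid.rmsecv[cs_grid.chosen_pair]),
            "rmsep": rmse,
            "bias_p": bias,
            "r2_p": r2,
            "selected": True,
        }
    )
    add_prediction(
        f"SO-CovSel ({first}->{second})",
        y_tr,
        _mb.socovsel_predict(cs_model, X_first[tr], X_second[tr]),
        y_te,
        yhat_te,
    )
    socovsel_selection = {
        "n_pair": cs_grid.chosen_pair,
        first: [int(reduced[first]["kept"][j]) for j in cs_model.selected_first],
        second: [int(reduced[second]["kept"][j]) for j in cs_model.selected_second],
    }

    return RunReport(
        config=config,
        rows=rows,
        train_ids=split.train_ids,
        test_ids=split.test_ids,
        best_single={b: info["label"] for b, info in best_single.items()},
        sopls_lv_pair=grid.chosen_pair,
        sopls_order_report=order_report,
        socovsel_selection=socovsel_selection,
        vip_counts=vip_counts,
        predictions=predictions,
    )


def report_to_csv(report: RunReport, path) -> None:
    """Write the consolidated model table as tidy CSV."""
    report.to_frame().to_csv(path, index=False)


def prediction_tables(report: RunReport, directory) -> None:
    """Write per-model predicted-vs-measured tables (train/test rows, the
    actual-fit slope/intercept of the test predictions, and the ideal
    slope-1/intercept-0 line) for scatter diagnostics."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for label, frame in report.predictions.items():
        safe = "".join(c if c.isalnum() else "_" for c in label).strip("_")
        test = frame[frame["set"] == "test"]
        slope, intercept = np.polyfit(test["ee_true"], test["ee_pred"], 1)
        frame = frame.copy()
        frame["fit_slope"] = slope
        frame["fit_intercept"] = intercept
        frame["ideal_slope"] = 1.0
        frame["ideal_intercept"] = 0.0
        frame.to_csv(directory / f"{safe}.csv", index=False)
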