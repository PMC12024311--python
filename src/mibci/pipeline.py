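"""End-to-end run: synthesize -> featurize -> search/train -> evaluate -> analyze.

Every stage consumes a seed derived from the global seed and the stage name,
all intermediate artifacts are written under the output directory, and a
manifest records the configuration, the per-stage seeds and the headline
metrics — rerunning with the same configuration reproduces every number.
"""
from __future__ import annotations

import json
import platform
from pathlib import Path

from . import __version__
from .bundle import ModelBundle
from .config import PipelineConfig, stage_seed
from .erders import analyze_session, render_reports
from .errors import MibciError
from .features import DEFAULT_STATS, make_windows
from .io import write_acquisition_csv
from .models import (
    HyperparamGrid,
    ModelKind,
    compare_models,
    evaluate as evaluate_model,
    search_wpt_model,
    train_classifier,
    ModelConfig,
)
from .features import Zscaler, WPTSearchSpace
from .protocol import ProtocolSpec
from .synth import NoiseModel, make_session_fixture


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage; returns the artifact directory.

    On a stage failure the partial manifest (with the failing stage named) is
    persisted before the error propagates.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "python": platform.python_version(),
        "stage_seeds": {},
        "stages_completed": [],
        "metrics": {},
    }

    def checkpoint(stage: str | None = None, error: str | None = None) -> None:
        if stage:
            manifest["stages_completed"].append(stage)
        if error:
            manifest["failed"] = error
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "synthesize"
    try:
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        protocol = ProtocolSpec(
            config.protocol.repetitions,
            config.protocol.segment_s,
            config.protocol.rest_s,
            config.protocol.module,
        )
        tables = make_session_fixture(
            config.synthesis.n_subjects,
            seed=seed,
            protocol=protocol,
            depth=config.synthesis.erd_depth,
            fs=config.synthesis.fs,
            window_s=config.synthesis.window_s,
            step_s=config.synthesis.step_s,
            noise_model=NoiseModel(
                rms_uv=config.synthesis.rms_uv, osc_power=dict(config.synthesis.osc_power)
            ),
        )
        fixture_dir = out / "fixtures"
        fixture_dir.mkdir(exist_ok=True)
        for i, t in enumerate(tables):
            write_acquisition_csv(t, fixture_dir / f"subject{i + 1:02d}.csv")
        checkpoint(stage)

        stage = "featurize"
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        windows = make_windows(tables, config.feature.window_rows, config.feature.hop_rows)
        manifest["metrics"]["n_windows"] = int(windows.n_windows)
        checkpoint(stage)

        stage = "search"
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        search = search_wpt_model(
            windows,
            space=WPTSearchSpace(),
            grid=HyperparamGrid(),
            n_iter=config.model.n_search_iter,
            seed=seed,
        )
        manifest["metrics"]["search_best_wavelet"] = search.best_spec.wavelet_name
        manifest["metrics"]["search_best_level"] = search.best_spec.level
        manifest["metrics"]["search_hyperparams"] = search.hyperparams
        manifest["metrics"]["wpt_nn_cv_accuracy"] = search.cv_result.mean_accuracy
        manifest["metrics"]["wpt_nn_fold_accuracies"] = search.cv_result.fold_accuracies
        checkpoint(stage)

        stage = "train"
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        X = windows.wavelet_features(search.best_spec)
        scaler = Zscaler().fit(X)
        model = train_classifier(
            X,
            windows.labels,
            ModelConfig(ModelKind(config.model.kind), dict(search.hyperparams), seed=seed),
            scaler=scaler,
        )
        bundle = ModelBundle(
            model=model,
            wavelet_spec=search.best_spec,
            stats=DEFAULT_STATS,
            column_names=windows.column_names,
            window_rows=config.feature.window_rows,
            hop_rows=config.feature.hop_rows,
        )
        bundle.save(out / "model_bundle")
        cm = evaluate_model(model, X, windows.labels)
        manifest["metrics"]["training_accuracy"] = cm.accuracy
        import pandas as pd

        pd.DataFrame(
            cm.counts, index=[str(c) for c in cm.classes], columns=[str(c) for c in cm.classes]
        ).to_csv(out / "confusion_matrix.csv")
        checkpoint(stage)

        stage = "compare"
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        board = compare_models(windows, seed=seed, wavelet_spec=search.best_spec,
                               hyperparams=search.hyperparams)
        board.to_frame().to_csv(out / "leaderboard.csv", index=False)
        manifest["metrics"]["leaderboard"] = {
            kind.value: acc for kind, acc in board.ranking()
        }
        checkpoint(stage)

        stage = "analyze"
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        results = analyze_session(
            tables[0],
            repetitions=config.protocol.repetitions,
            bands=tuple(config.analysis.bands),
            edge_trim_s=config.analysis.edge_trim_s,
        )
        render_reports(results, out / "erd_ers")
        checkpoint(stage)
    except MibciError as exc:
        checkpoint(error=f"stage {stage!r}: {exc}")
        raise
    return out
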