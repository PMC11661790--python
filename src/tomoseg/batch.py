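"""Batch segmentation over many (model, volume) pairs.

Designed for unattended runs: every pair of a trained model bundle and an
input tomogram is segmented; interactions/competition from the run config
are then applied per volume across the resulting feature predictions; one
prediction MRC per feature per volume is written, named
``<volume-stem>_<feature>.mrc``.  Failing items are logged and skipped; the
result records them so callers can signal partial failure.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .config import RunConfig, load_config
from .interactions import apply_pipeline
from .io import read_mrc, write_mrc
from .models import load_model, segment_volume

__all__ = ["BatchResult", "run_batch_segment"]

log = logging.getLogger(__name__)


@dataclass
class BatchResult:
    written: list[Path] = field(default_factory=list)
    failed: list[tuple[str, str]] = field(default_factory=list)  # (item, reason)

    @property
    def ok(self) -> bool:
        return not self.failed


def run_batch_segment(
    model_paths: list,
    volume_paths: list,
    pipeline_config=None,
    out_dir=".",
    stride: int | None = None,
    seed: int = 0,
) -> BatchResult:
    """Segment every (model, volume) pair and write per-feature MRCs.

    ``pipeline_config`` is a path to a TOML run config or a
    :class:`~tomoseg.config.RunConfig`; its competition/interaction sections
    are applied to each volume's feature predictions before writing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_log = out_dir / "run.log"
    handler = logging.FileHandler(run_log)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("tomoseg")
    root.addHandler(handler)
    result = BatchResult()
    try:
        log.info("tomoseg %s batch segmentation: %d models x %d volumes, seed %d",
                 __version__, len(model_paths), len(volume_paths), seed)
        if pipeline_config is None:
            cfg = RunConfig()
        elif isinstance(pipeline_config, RunConfig):
            cfg = pipeline_config
        else:
            cfg = load_config(pipeline_config)

        models = {}
        for mp in model_paths:
            try:
                model = load_model(mp)
                name = model.feature_name or Path(mp).stem
                models[name] = model
            except Exception as exc:  # noqa: BLE001 - batch isolation
                log.error("failed to load model %s: %s", mp, exc)
                result.failed.append((str(mp), f"model load failed: {exc}"))

        for vp in volume_paths:
            try:
                volume = read_mrc(vp)
            except Exception as exc:  # noqa: BLE001
                log.error("failed to read volume %s: %s", vp, exc)
                result.failed.append((str(vp), f"volume read failed: {exc}"))
                continue
            preds = {}
            for feature, model in models.items():
                t0 = time.perf_counter()
                try:
                    preds[feature] = segment_volume(model, volume, stride=stride)
                    log.info("segmented %s / %s in %.1f s", Path(vp).name, feature,
                             time.perf_counter() - t0)
                except Exception as exc:  # noqa: BLE001
                    log.error("segmentation failed for %s / %s: %s", vp, feature, exc)
                    result.failed.append((f"{vp}:{feature}", f"segmentation failed: {exc}"))
            if not preds:
                continue
            needed = {s.parent_feature for s in cfg.interactions}
            needed |= {s.child_feature for s in cfg.interactions}
            if cfg.competition is not None or (cfg.interactions and needed <= set(preds)):
                preds = apply_pipeline(preds, cfg.competition, cfg.interactions)
            for feature, pred in preds.items():
                out_path = out_dir / f"{Path(vp).stem}_{feature}.mrc"
                write_mrc(pred, out_path)
                result.written.append(out_path)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
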