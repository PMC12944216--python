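"""End-to-end orchestration: mask -> normalize -> segment -> waves.

Stages communicate only through the declared containers/file formats, so any
stage can also be run standalone on externally produced inputs.  A run
manifest records every stage's parameters, library versions and the seed;
identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import __version__
from .io import StimulusProtocol, TimelapseStack, write_results
from .mask import ColonyMasker
from .normalize import StackNormalizer
from .segment import ROISegmenter, exclude_nonresponsive
from .waves import PulseMetrics, WaveDetector, pulse_metrics

__all__ = ["RunConfig", "MossWavePipeline", "run_all"]


@dataclass
class RunConfig:
    """All stage parameters with their defaults, JSON round-trippable."""

    # mask stage
    bg_radius_px: float = 25.0
    median_radius_px: float = 2.5
    mask_min_area_px2: int = 200
    circularity_limit: float = 0.9
    circularity_mode: str = "exclude_round"
    # normalize stage
    psf_diameter_um: float = 1.1
    deconvolution_iterations: int = 10
    opening_radius_px: int = 15
    background_stride: int = 1
    # segment stage
    mean_roi_area_px2: int = 150
    roi_min_area_px2: int = 12
    kmeans_replicates: int = 10
    baseline_percentile: float = 1.0
    # wave stage
    prominence_factor: float = 0.35
    min_prominence: float = 0.3
    merge_window_s: float = 10.0
    # exclusion rule
    exclude_nonresponsive: bool = True
    response_threshold: float = 1.0
    response_window_s: float = 300.0
    # run
    seed: int = 0

    @classmethod
    def from_json(cls, path_or_obj: str | Path | dict) -> "RunConfig":
        obj = (
            path_or_obj
            if isinstance(path_or_obj, dict)
            else json.loads(Path(path_or_obj).read_text())
        )
        known = {f.name for f in fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True, indent=1) + "\n")


class MossWavePipeline(BaseEstimator):
    """Full analysis pipeline as a composite estimator.

    ``fit(stack, protocol=...)`` runs masking, normalization, segmentation,
    trace extraction, the non-responsive-ROI exclusion rule, wave detection
    and pulse metrics.  Fitted attributes: ``masker_``, ``normalizer_``,
    ``segmenter_``, ``traces_``, ``detector_``, ``table_``,
    ``pulse_metrics_``, ``exclusions_``, ``manifest_``.
    """

    def __init__(self, config: RunConfig | None = None):
        self.config = config

    def fit(self, X: TimelapseStack, y=None, protocol: StimulusProtocol | None = None) -> "MossWavePipeline":
        cfg = self.config or RunConfig()

        def stage(name, fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"[{name}] {exc}") from exc

        masker = ColonyMasker(
            bg_radius_px=cfg.bg_radius_px,
            median_radius_px=cfg.median_radius_px,
            min_area_px2=cfg.mask_min_area_px2,
            circularity_limit=cfg.circularity_limit,
            circularity_mode=cfg.circularity_mode,
        )
        stage("mask", lambda: masker.fit(X))

        normalizer = StackNormalizer(
            psf_diameter_um=cfg.psf_diameter_um,
            iterations=cfg.deconvolution_iterations,
            opening_radius_px=cfg.opening_radius_px,
            background_stride=cfg.background_stride,
        )
        stage("normalize", lambda: normalizer.fit(X, mask=masker.mask_))

        segmenter = ROISegmenter(
            mean_roi_area_px2=cfg.mean_roi_area_px2,
            min_area_px2=cfg.roi_min_area_px2,
            replicates=cfg.kmeans_replicates,
            random_state=cfg.seed,
            baseline_percentile=cfg.baseline_percentile,
        )
        stage("segment", lambda: segmenter.fit(normalizer.zstack_))
        traces = stage("segment", lambda: segmenter.extract(normalizer.corrected_))

        exclusions: list[dict] = []
        if cfg.exclude_nonresponsive and protocol is not None and protocol.n_pulses:
            traces, exclusions = stage(
                "exclude",
                lambda: exclude_nonresponsive(
                    traces, protocol, cfg.response_threshold, cfg.response_window_s
                ),
            )

        detector = WaveDetector(
            prominence_factor=cfg.prominence_factor,
            min_prominence=cfg.min_prominence,
            merge_window_s=cfg.merge_window_s,
        )
        stage("waves", lambda: detector.fit(traces))
        if len(detector.table_) == 0:
            warnings.warn("no calcium waves detected in any ROI", stacklevel=2)

        pm: PulseMetrics | None = None
        if protocol is not None and protocol.n_pulses:
            pm = stage("pulse_metrics", lambda: pulse_metrics(detector.table_, traces, protocol))

        import scipy
        import skimage
        import sklearn

        self.masker_ = masker
        self.normalizer_ = normalizer
        self.segmenter_ = segmenter
        self.traces_ = traces
        self.detector_ = detector
        self.table_ = detector.table_
        self.pulse_metrics_ = pm
        self.exclusions_ = exclusions
        self.manifest_ = {
            "config": asdict(cfg),
            "seed": cfg.seed,
            "n_foreground_px": masker.mask_.n_foreground,
            "initial_k": segmenter.initial_k_,
            "n_rois": segmenter.n_rois_,
            "n_rois_retained": traces.n_rois,
            "n_waves": len(detector.table_),
            "excluded_rois": exclusions,
            "versions": {
                "mosswave": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "scikit-image": skimage.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
        return self

    def save(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        manifest = write_results(self.traces_, self.table_, outdir,
                                 manifest_extra=self.manifest_)
        return manifest


def run_all(
    stack: TimelapseStack,
    protocol: StimulusProtocol | None = None,
    config: RunConfig | None = None,
):
    """Run the full pipeline; returns
    (label_map, traces, wave_table, pulse_metrics, manifest)."""
    pipe = MossWavePipeline(config=config).fit(stack, protocol=protocol)
    return (
        pipe.segmenter_.labels_,
        pipe.traces_,
        pipe.table_,
        pipe.pulse_metrics_,
        pipe.manifest_,
    )
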