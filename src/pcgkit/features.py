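"""Signal -> irregularity feature, as a scikit-learn transformer.

Chains the stages: peak normalization, windowed Katz FD profile,
FD-threshold event detection, S1/S2 labeling, cycle extraction, and
per-cycle sample entropy averaged into one scalar feature per record.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .entropy import FeatureVector, SampEnConfig, irregularity_index, sample_entropy
from .io import AudioSignal, normalize
from .segmentation import segment_signal

__all__ = ["extract_feature", "IrregularityExtractor"]

logger = logging.getLogger(__name__)


def extract_feature(
    signal: AudioSignal,
    cfg: SampEnConfig = SampEnConfig(),
    window_s: float = 0.05,
    overlap: float = 0.99,
    k_sigma: float = 0.5,
    min_event_s: float = 0.04,
    merge_gap_s: float = 0.03,
    whole_record: bool = False,
    fallback_whole_record: bool = True,
) -> FeatureVector:
    """Irregularity feature of one recording.

    The signal is peak-normalized, segmented into cardiac cycles via the
    FD profile, and the per-cycle sample entropies are averaged. With
    ``whole_record=True`` segmentation is skipped and SampEn is computed
    on the full record instead. When segmentation finds no usable cycle
    (heavy noise can bury the FD peaks) and *fallback_whole_record* is
    set, the whole-record SampEn is used and the fallback is logged;
    otherwise the error propagates.
    """
    sig = normalize(signal)
    if not whole_record:
        cycles = segment_signal(
            sig,
            window_s=window_s,
            overlap=overlap,
            k_sigma=k_sigma,
            min_event_s=min_event_s,
            merge_gap_s=merge_gap_s,
        )
        usable = [seg for _, seg in cycles if seg.size > cfg.m + 1]
        if usable:
            try:
                return irregularity_index(sig, usable, cfg)
            except ValueError:
                if not fallback_whole_record:
                    raise
        elif not fallback_whole_record:
            raise ValueError(f"{sig.source_id}: no usable cardiac cycle")
        logger.info(
            "%s: segmentation yielded no usable cycle; falling back to "
            "whole-record sample entropy",
            sig.source_id,
        )
    value = sample_entropy(sig.samples, cfg)
    if not np.isfinite(value):
        raise ValueError(f"{sig.source_id}: whole-record sample entropy undefined")
    return FeatureVector(
        source_id=sig.source_id, sampen=float(value), n_cycles_used=0, label=sig.label
    )


class IrregularityExtractor(TransformerMixin, BaseEstimator):
    """Transform a list of :class:`AudioSignal` into a (n, 1) feature matrix.

    Stateless (``fit`` only validates); exists so the whole pipeline
    composes with scikit-learn model selection:

    >>> pipe = make_pipeline(IrregularityExtractor(), HeartSoundSVC())

    Parameters mirror :func:`extract_feature`.
    """

    def __init__(
        self,
        m: int = 2,
        r: float = 0.2,
        r_mode: str = "absolute",
        window_s: float = 0.05,
        overlap: float = 0.99,
        k_sigma: float = 0.5,
        min_event_s: float = 0.04,
        merge_gap_s: float = 0.03,
        whole_record: bool = False,
    ) -> None:
        self.m = m
        self.r = r
        self.r_mode = r_mode
        self.window_s = window_s
        self.overlap = overlap
        self.k_sigma = k_sigma
        self.min_event_s = min_event_s
        self.merge_gap_s = merge_gap_s
        self.whole_record = whole_record

    def _cfg(self) -> SampEnConfig:
        return SampEnConfig(m=self.m, r=self.r, r_mode=self.r_mode)

    def fit(self, X, y=None):
        self._cfg()  # parameter validation
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        feats = [
            extract_feature(
                sig,
                cfg=self._cfg(),
                window_s=self.window_s,
                overlap=self.overlap,
                k_sigma=self.k_sigma,
                min_event_s=self.min_event_s,
                merge_gap_s=self.merge_gap_s,
                whole_record=self.whole_record,
            ).sampen
            for sig in X
        ]
        return np.asarray(feats, dtype=np.float64)[:, None]
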