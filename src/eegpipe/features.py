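"""Per-window feature vectors assembled across the analysis channels.

For one feature type, the windows of a subject at a given window index are
combined across the five analysis channels into a single feature vector:
ApEn and fractal dimension contribute one value per channel, the AR model
``P`` coefficients per channel, and band power four values per channel.
The resulting matrix carries subject ids and group labels so the
leave-one-participant-out folds can be built without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complexity import ApEnParams, HiguchiParams, apen, higuchi_fd
from .exceptions import ValidationError
from .io import WindowingParams, segment
from .recording import GROUP_PATIENT
from .spectral import EEG_BANDS, band_power, burg_ar

__all__ = ["FEATURE_TYPES", "FeatureMatrix", "extract_feature_matrix"]

FEATURE_TYPES = ("apen", "ar", "band_power", "fractal_dimension")

#: Accepted aliases on the CLI and in configs.
_ALIASES = {
    "apen": "apen",
    "ar": "ar",
    "bp": "band_power",
    "band_power": "band_power",
    "fd": "fractal_dimension",
    "fractal_dimension": "fractal_dimension",
}


def canonical_feature_type(name: str) -> str:
    try:
        return _ALIASES[name.lower()]
    except KeyError:
        raise ValidationError(
            f"unknown feature type {name!r}; expected one of {sorted(_ALIASES)}"
        ) from None


@dataclass
class FeatureMatrix:
    """Window-level design matrix for one feature type.

    ``y`` uses +1 for patients and -1 for controls, fixing sensitivity as
    the patient detection rate.
    """

    feature_type: str
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    subjects: np.ndarray = field(repr=False)
    window_index: np.ndarray = field(repr=False)
    feature_names: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D (windows x features)")
        if not (len(self.y) == len(self.subjects) == self.X.shape[0]):
            raise ValidationError("X, y and subjects must have equal length")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subject_id, group, window_index, feature, value."""
        wide = pd.DataFrame(self.X, columns=self.feature_names)
        wide.insert(0, "subject_id", self.subjects)
        wide.insert(1, "group", np.where(self.y > 0, "patient", "control"))
        wide.insert(2, "window_index", self.window_index)
        return wide.melt(
            id_vars=["subject_id", "group", "window_index"],
            var_name="feature_name",
            value_name="value",
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, feature_type: str) -> "FeatureMatrix":
        """Rebuild the design matrix from the long-format table."""
        wide = frame.pivot_table(
            index=["subject_id", "group", "window_index"],
            columns="feature_name",
            values="value",
            sort=False,
        ).reset_index()
        names = [c for c in wide.columns if c not in ("subject_id", "group", "window_index")]
        return cls(
            feature_type=feature_type,
            X=wide[names].to_numpy(dtype=float),
            y=np.where(wide["group"].to_numpy() == GROUP_PATIENT, 1, -1),
            subjects=wide["subject_id"].to_numpy(),
            window_index=wide["window_index"].to_numpy(),
            feature_names=names,
        )


def _window_features(w, feature_type, apen_params, higuchi_params, ar_order, bands):
    if feature_type == "apen":
        return {f"apen_{w.channel}": apen(w.samples, apen_params).value}
    if feature_type == "fractal_dimension":
        return {f"fd_{w.channel}": higuchi_fd(w.samples, higuchi_params).dimension}
    if feature_type == "ar":
        model = burg_ar(w.samples, order=ar_order)
        return {
            f"ar{i + 1}_{w.channel}": c for i, c in enumerate(model.coefficients)
        }
    if feature_type == "band_power":
        bp = band_power(w.samples, w.fs, bands)
        return {f"{name}_{w.channel}": p for name, p in bp.powers.items()}
    raise ValidationError(f"unknown feature type {feature_type!r}")


def extract_feature_matrix(
    recordings,
    feature_type: str,
    windowing: WindowingParams = WindowingParams(),
    apen_params: ApEnParams = ApEnParams(),
    higuchi_params: HiguchiParams = HiguchiParams(),
    ar_order: int = 10,
    bands=EEG_BANDS,
) -> FeatureMatrix:
    """Window every recording and compute one feature type across channels.

    Returns one row per (subject, window index) with the channels'
    features concatenated in channel order.
    """
    feature_type = canonical_feature_type(feature_type)
    rows, labels, subjects, indices = [], [], [], []
    feature_names = None
    for rec in recordings:
        per_index: dict[int, dict] = {}
        for w in segment(rec, windowing):
            per_index.setdefault(w.index, {}).update(
                _window_features(
                    w, feature_type, apen_params, higuchi_params, ar_order, bands
                )
            )
        for idx in sorted(per_index):
            feats = per_index[idx]
            if feature_names is None:
                feature_names = list(feats)
            rows.append([feats[name] for name in feature_names])
            labels.append(1 if rec.group == GROUP_PATIENT else -1)
            subjects.append(rec.subject_id)
            indices.append(idx)
    return FeatureMatrix(
        feature_type=feature_type,
        X=np.array(rows),
        y=np.array(labels),
        subjects=np.array(subjects),
        window_index=np.array(indices),
        feature_names=feature_names or [],
    )
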