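"""JSON serialization of fitted signature models.

A signature travels as plain JSON: the selected feature names, the 0-100
score scaling, and every tree of the forest as flat node-record arrays
(split feature index, threshold, child pointers, per-node risk).  The
deserialized object predicts by traversing those records, so a scored
cohort does not need the original fitted forest — `score` works from the
JSON file alone and reproduces the in-memory scores exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import SignatureModel, signature_score

__all__ = ["signature_to_json", "SerializedSignature", "load_signature"]


def signature_to_json(model: SignatureModel, path: str | Path) -> None:
    """Write a fitted signature (trees as nested split records) to JSON."""
    trees = []
    for est, leaf_risk in zip(model.rsf.forest.estimators_, model.rsf.leaf_risk):
        t = est.tree_
        trees.append({
            "feature": t.feature.tolist(),          # -2 marks a leaf
            "threshold": t.threshold.tolist(),
            "left": t.children_left.tolist(),
            "right": t.children_right.tolist(),
            "risk": np.asarray(leaf_risk).tolist(),
        })
    payload = {
        "pool": model.pool,
        "features": model.features,
        "score_min": model.score_min,
        "score_max": model.score_max,
        "trees": trees,
    }
    Path(path).write_text(json.dumps(payload))


@dataclass
class SerializedSignature:
    """A signature reloaded from JSON; predicts via stored node records."""

    pool: str
    features: list[str]
    score_min: float
    score_max: float
    trees: list[dict]

    def _tree_risk(self, tree: dict, X: np.ndarray) -> np.ndarray:
        feature = np.asarray(tree["feature"])
        threshold = np.asarray(tree["threshold"])
        left = np.asarray(tree["left"])
        right = np.asarray(tree["right"])
        risk = np.asarray(tree["risk"])
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = 0
            while feature[node] >= 0:
                node = left[node] if row[feature[node]] <= threshold[node] else right[node]
            out[i] = risk[node]
        return out

    def predict_mortality(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"feature table lacks signature feature(s): {missing}")
        # sklearn trees compare against float32-cast inputs
        Xa = X[self.features].to_numpy(dtype=np.float32).astype(float)
        return np.mean([self._tree_risk(t, Xa) for t in self.trees], axis=0)

    def score(self, X: pd.DataFrame) -> np.ndarray:
        raw = self.predict_mortality(X)
        s = 100.0 * (raw - self.score_min) / (self.score_max - self.score_min)
        return np.clip(s, 0.0, 100.0)


def load_signature(path: str | Path) -> SerializedSignature:
    d = json.loads(Path(path).read_text())
    return SerializedSignature(
        pool=d["pool"], features=d["features"],
        score_min=d["score_min"], score_max=d["score_max"], trees=d["trees"],
    )
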