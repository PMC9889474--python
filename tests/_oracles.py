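"""Independent brute-force oracles used by the tests.

These deliberately use naive enumeration (voxel loops, pair loops) so
they share no code path with the implementations they check.
"""
from __future__ import annotations

import numpy as np

ALL_OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def glcm_brute(levels: np.ndarray, offset) -> dict[str, float] | None:
    """Per-offset GLCM features by explicit pair enumeration (levels 0 = outside)."""
    K = int(levels.max())
    P = np.zeros((K, K))
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                u, v, w = x + dx, y + dy, z + dz
                if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                    continue
                b = levels[u, v, w]
                if b == 0:
                    continue
                P[a - 1, b - 1] += 1
                P[b - 1, a - 1] += 1
    if P.sum() == 0:
        return None
    P /= P.sum()
    i = np.arange(1, K + 1)[:, None]
    j = np.arange(1, K + 1)[None, :]
    px = P.sum(axis=1)
    mu = float((np.arange(1, K + 1) * px).sum())
    sig2 = float(((np.arange(1, K + 1) - mu) ** 2 * px).sum())
    nzm = P > 0
    out = {
        "contrast": float((P * (i - j) ** 2).sum()),
        "dissimilarity": float((P * np.abs(i - j)).sum()),
        "energy": float((P**2).sum()),
        "homogeneity": float((P / (1 + (i - j) ** 2)).sum()),
        "entropy": float(-(P[nzm] * np.log(P[nzm])).sum()),
    }
    out["correlation"] = (
        float(((i - mu) * (j - mu) * P).sum() / sig2) if sig2 > 0 else None
    )
    return out


def glrlm_brute(levels: np.ndarray, direction) -> np.ndarray:
    """Run-length matrix by walking every line in the given direction."""
    K = int(levels.max())
    max_len = max(levels.shape)
    R = np.zeros((K, max_len))
    nx, ny, nz = levels.shape
    dx, dy, dz = direction

    def inside(p):
        return 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz

    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lvl = levels[x, y, z]
                if lvl == 0:
                    continue
                prev = (x - dx, y - dy, z - dz)
                if inside(prev) and levels[prev] == lvl:
                    continue  # not a run start
                length = 1
                cur = (x + dx, y + dy, z + dz)
                while inside(cur) and levels[cur] == lvl:
                    length += 1
                    cur = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
                R[lvl - 1, length - 1] += 1
    return R


def glrlm_features_brute(levels: np.ndarray, n_vox: int) -> dict[str, float]:
    """Direction-averaged run-length features from the brute-force matrices."""
    feats = {k: [] for k in ("sre", "lre", "gln", "rln", "run_percentage", "run_entropy")}
    for d in ALL_OFFSETS_13:
        R = glrlm_brute(levels, d)
        n_runs = R.sum()
        if n_runs == 0:
            continue
        jj = np.arange(1, R.shape[1] + 1)
        row, col = R.sum(axis=1), R.sum(axis=0)
        p = R[R > 0] / n_runs
        feats["sre"].append((col / jj**2).sum() / n_runs)
        feats["lre"].append((col * jj**2).sum() / n_runs)
        feats["gln"].append((row**2).sum() / n_runs)
        feats["rln"].append((col**2).sum() / n_runs)
        feats["run_percentage"].append(n_runs / n_vox)
        feats["run_entropy"].append(-(p * np.log(p)).sum())
    return {k: float(np.mean(v)) for k, v in feats.items()}


def cindex_brute(risk, time, event) -> float:
    """O(n^2) Harrell C: shorter-time-event pairs, 0.5 for risk ties."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def km_brute(time, event, grid) -> np.ndarray:
    """Product-limit estimator evaluated at the given times."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    out = []
    for t in grid:
        s = 1.0
        for u in np.unique(time[event & (time <= t)]):
            d = int(((time == u) & event).sum())
            n_at_risk = int((time >= u).sum())
            s *= 1 - d / n_at_risk
        out.append(s)
    return np.asarray(out)
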