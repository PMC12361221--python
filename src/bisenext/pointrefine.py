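"""PointRefine: uncertainty-driven point decoding.

A coarse low-resolution prediction is refined only where it is unsure.
Per-pixel uncertainty is the negated gap between the two largest class
logits (a zero gap is maximal uncertainty).  At each refinement step,
``j*N`` uniform candidate locations are scored, the ``floor(beta*N)`` most
uncertain are kept (ties broken by candidate index), and the remaining
points are drawn uniformly so exactly ``N`` points are re-labelled by a
small MLP over bilinearly sampled fine-grained features concatenated with
the coarse logits.  At inference the map is upsampled x2 and re-pointed
``m`` times before the final resize to full resolution; pixels never
selected keep their bilinear values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import PointParams
from .nn import autograd as A


@dataclass
class PointSet:
    """Sampled refinement points in normalised [0,1]^2 coordinates (x, y)."""

    coords: np.ndarray           # (B, N, 2)
    uncertainties: np.ndarray    # (B, N); random fill-in points carry -inf gap scores
    point_logits: np.ndarray | None = None   # (B, N, K) once predicted

    def __len__(self) -> int:
        return self.coords.shape[1]


def uncertainty_map(logits) -> np.ndarray:
    """Per-pixel score = -(top1 - top2) over the class axis; higher = less sure.

    ``logits``: array or Tensor of shape (B, K, H, W) or (K, H, W), K >= 2.
    """
    arr = logits.data if isinstance(logits, A.Tensor) else np.asarray(logits)
    axis = 0 if arr.ndim == 3 else 1
    if arr.shape[axis] < 2:
        raise ValueError("uncertainty requires at least 2 classes")
    part = np.partition(arr, -2, axis=axis)
    top2 = np.take(part, [-2, -1], axis=axis)
    gap = np.abs(np.diff(top2, axis=axis))
    return -np.squeeze(gap, axis=axis)


def sample_points(coarse_logits, params: PointParams,
                  rng: np.random.Generator | int) -> PointSet:
    """Draw ``j*N`` uniform candidates, keep the floor(beta*N) most uncertain
    (stable order), and top up with fresh uniform points to exactly N."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arr = coarse_logits.data if isinstance(coarse_logits, A.Tensor) else np.asarray(coarse_logits)
    B = arr.shape[0]
    n_ranked, n_random = params.n_ranked, params.n_random
    coords = np.empty((B, params.n, 2), dtype=np.float64)
    unc = np.full((B, params.n), -np.inf)
    cand = rng.uniform(0.0, 1.0, size=(B, params.j * params.n, 2))
    if n_ranked:
        scores = _point_uncertainty(arr, cand)
        # stable sort on descending score = ascending on negated score
        order = np.argsort(-scores, axis=1, kind="stable")[:, :n_ranked]
        bi = np.arange(B)[:, None]
        coords[:, :n_ranked] = cand[bi, order]
        unc[:, :n_ranked] = scores[bi, order]
    if n_random:
        coords[:, n_ranked:] = rng.uniform(0.0, 1.0, size=(B, n_random, 2))
    return PointSet(coords=coords, uncertainties=unc)


def _point_uncertainty(logits: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Uncertainty of bilinearly interpolated logits at (B, M, 2) coords."""
    with A.no_grad():
        sampled = A.point_sample(A.Tensor(logits), coords).data   # (B, K, M)
    part = np.partition(sampled, -2, axis=1)
    return -(part[:, -1] - part[:, -2])


class PointHead(nn.Module):
    """Shared per-point relabeller.

    Fine features pass one fully connected layer, are concatenated with the
    point's coarse logits, and a 3-hidden-layer MLP emits class logits
    independently per point, as a residual on the interpolated coarse logits.
    """

    def __init__(self, fine_channels: int, num_classes: int, fc_dim: int = 128,
                 hidden: int = 128, n_hidden: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.num_classes = num_classes
        self.fc = nn.Linear(fine_channels, fc_dim, rng=rng)
        layers: list[nn.Module] = []
        d = fc_dim + num_classes
        for _ in range(n_hidden):
            layers.append(nn.Linear(d, hidden, rng=rng))
            layers.append(nn.ReLU())
            d = hidden
        final = nn.Linear(d, num_classes, rng=rng)
        # zero-init the residual output: refinement starts as the identity on
        # the interpolated coarse logits and only learns corrections
        final.weight.data[...] = 0.0
        final.bias.data[...] = 0.0
        layers.append(final)
        self.mlp = nn.Sequential(*layers)

    def forward(self, fine_features, coarse_logits, points: PointSet):
        """-> Tensor of refined logits, shape (B, N, num_classes)."""
        coords = points.coords
        if coords.shape[1] == 0:
            B = coords.shape[0]
            return A.Tensor(np.zeros((B, 0, self.num_classes), dtype=np.float32))
        f = A.point_sample(A.as_tensor(fine_features), coords)    # (B, Cf, N)
        f = A.relu(self.fc(A.transpose(f, (0, 2, 1))))            # (B, N, fc)
        c = A.transpose(A.point_sample(A.as_tensor(coarse_logits), coords), (0, 2, 1))
        # residual head: the MLP predicts a correction to the interpolated
        # coarse logits, so confident regions are never overturned by noise
        return self.mlp(A.concat([f, c], axis=2)) + c             # (B, N, K)


def scatter_points(logit_map: np.ndarray, points: PointSet,
                   point_logits: np.ndarray) -> np.ndarray:
    """Write per-point logits into the nearest pixels of (B, K, H, W).

    Later points win coordinate collisions (deterministic).  Returns a copy.
    """
    out = logit_map.copy()
    B, K, H, W = out.shape
    ix = np.clip(np.floor(points.coords[..., 0] * W).astype(int), 0, W - 1)
    iy = np.clip(np.floor(points.coords[..., 1] * H).astype(int), 0, H - 1)
    for b in range(B):
        flat = iy[b] * W + ix[b]
        # keep only the last occurrence of each pixel
        _, last = np.unique(flat[::-1], return_index=True)
        keep = len(flat) - 1 - last
        out[b].reshape(K, H * W)[:, flat[keep]] = point_logits[b, keep].T
    return out


def snap_to_grid(points: PointSet, grid_shape: tuple[int, int]) -> PointSet:
    """Move each point to the centre of its nearest pixel on (H, W)."""
    H, W = grid_shape
    ix = np.clip(np.floor(points.coords[..., 0] * W), 0, W - 1)
    iy = np.clip(np.floor(points.coords[..., 1] * H), 0, H - 1)
    snapped = np.stack([(ix + 0.5) / W, (iy + 0.5) / H], axis=-1)
    return PointSet(coords=snapped, uncertainties=points.uncertainties,
                    point_logits=points.point_logits)


def refine(main_logits, fine_features, head: PointHead, params: PointParams,
           rng: np.random.Generator | int, out_size: tuple[int, int]) -> np.ndarray:
    """Iterative inference-time refinement.

    Repeats ``m`` times: bilinear x2 upsample, sample N points on the current
    (already partially refined) map, relabel them with the point head and
    scatter the new logits in place; finally upsamples to ``out_size``.
    Sampled points are snapped to pixel centres of the current grid, so a
    head that predicts a zero correction leaves the map bit-identical.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    with A.no_grad():
        cur = (main_logits.data if isinstance(main_logits, A.Tensor)
               else np.asarray(main_logits)).astype(np.float32)
        fine = A.as_tensor(fine_features)
        for _ in range(params.m):
            B, K, H, W = cur.shape
            cur = A.interpolate_bilinear(A.Tensor(cur), (2 * H, 2 * W)).data
            pts = snap_to_grid(sample_points(cur, params, rng), cur.shape[2:])
            logits = head(fine, A.Tensor(cur), pts).data
            cur = scatter_points(cur, pts, logits)
        if cur.shape[2:] != tuple(out_size):
            cur = A.interpolate_bilinear(A.Tensor(cur), tuple(out_size)).data
    return cur


def point_loss(head: PointHead, fine_features, coarse_logits, truth_mask: np.ndarray,
               params: PointParams, rng: np.random.Generator | int):
    """Training-time point term: one sampling round, cross-entropy at points.

    Ground-truth labels are read at the nearest mask pixel of each point.
    Returns (loss Tensor, PointSet).
    """
    pts = sample_points(coarse_logits, params, rng)
    logits = head(fine_features, coarse_logits, pts)              # (B, N, K)
    B, N, K = logits.shape
    H, W = truth_mask.shape[-2:]
    ix = np.clip(np.floor(pts.coords[..., 0] * W).astype(int), 0, W - 1)
    iy = np.clip(np.floor(pts.coords[..., 1] * H).astype(int), 0, H - 1)
    labels = truth_mask[np.arange(B)[:, None], iy, ix].reshape(-1)
    flat = A.reshape(logits, (B * N, K))
    return A.cross_entropy(flat, labels), pts
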