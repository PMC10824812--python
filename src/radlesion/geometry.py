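"""Cell-nucleus domain geometry.

The nucleus is modelled as a closed, convex, bounded domain Q — a disk in
two dimensions or a ball in three.  Lesions live in the closure Q̄; Brownian
increments that would leave the domain are mapped back inside by specular
(radial-mirror) reflection.  All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Domain", "disk", "ball"]

_SHAPES = {"disk2d": 2, "ball3d": 3}


@dataclass(frozen=True)
class Domain:
    """Closed disk (2-D) or ball (3-D) of radius ``radius_um``.

    Parameters
    ----------
    shape : {"disk2d", "ball3d"}
    radius_um : float
        Radius R > 0 [μm].
    center : array-like, optional
        Centre coordinates [μm]; defaults to the origin.
    """

    shape: str
    radius_um: float
    center: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown domain shape {self.shape!r}")
        if not self.radius_um > 0:
            raise ValueError("domain radius must be positive")
        d = _SHAPES[self.shape]
        center = np.zeros(d) if self.center is None else np.asarray(self.center, float)
        if center.shape != (d,):
            raise ValueError(f"center must have dimension {d}")
        object.__setattr__(self, "center", center)

    @property
    def dimension(self) -> int:
        return _SHAPES[self.shape]

    def contains(self, point: np.ndarray) -> np.ndarray | bool:
        """Membership in the closure Q̄ (boundary included).

        Accepts a single point of shape ``(d,)`` or a batch ``(n, d)``.
        """
        pts = np.asarray(point, float)
        single = pts.ndim == 1
        if pts.shape[-1] != self.dimension:
            raise ValueError(
                f"point dimension {pts.shape[-1]} does not match domain dimension {self.dimension}"
            )
        r = np.linalg.norm(np.atleast_2d(pts) - self.center, axis=-1)
        inside = r <= self.radius_um
        return bool(inside[0]) if single else inside

    def reflect(self, proposed: np.ndarray) -> np.ndarray:
        """Map proposed diffusion endpoints back into Q̄ by radial mirroring.

        A point at radial distance ρ > R is replaced by one at 2R − ρ along
        the same ray, iterating until inside.  Interior and boundary points
        are returned unchanged.  Exact specular reflection for radial
        overshoot; first-order accurate in the Euler step size.
        """
        pts = np.atleast_2d(np.asarray(proposed, float)).copy()
        single = np.asarray(proposed).ndim == 1
        rel = pts - self.center
        for _ in range(64):
            r = np.linalg.norm(rel, axis=-1)
            out = r > self.radius_um
            if not out.any():
                break
            rel[out] *= ((2.0 * self.radius_um - r[out]) / r[out])[:, None]
            # |2R − ρ| handles pathological overshoots past the far boundary
            rel[out] = np.where(
                (2.0 * self.radius_um - r[out])[:, None] < 0, -rel[out], rel[out]
            )
        pts = self.center + rel
        return pts[0] if single else pts

    def uniform_sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw points uniformly on Q̄ by rejection from the bounding box."""
        n = 1 if size is None else int(size)
        d, R = self.dimension, self.radius_um
        out = np.empty((n, d))
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 16)
            cand = rng.uniform(-R, R, size=(m, d))
            keep = cand[np.linalg.norm(cand, axis=1) <= R]
            take = min(len(keep), n - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
        out += self.center
        return out[0] if size is None else out


def disk(radius_um: float = 5.0, center=None) -> Domain:
    """Convenience constructor for a 2-D disk nucleus (default R = 5 μm)."""
    return Domain("disk2d", radius_um, center)


def ball(radius_um: float = 5.0, center=None) -> Domain:
    """Convenience constructor for a 3-D ball nucleus."""
    return Domain("ball3d", radius_um, center)
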