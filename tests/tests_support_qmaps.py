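"""Shared synthetic maps for Q-score checks."""

import numpy as np

from cryoswim.densmap import DensityMap


class _AnalyticGaussianMap(DensityMap):
    """Evaluates the reference Gaussian profile exactly at any point; the
    grid only supplies bounds and map statistics."""

    def __init__(self, center, sigma_ref=0.6):
        rng = np.random.default_rng(0)
        super().__init__(rng.random((16, 16, 16)), 1.0, (0.0, 0.0, 0.0))
        self._center = np.asarray(center, float)
        self._sr = sigma_ref

    def interpolate(self, points):
        pts = np.atleast_2d(np.asarray(points, float))
        r2 = np.sum((pts - self._center) ** 2, axis=1)
        vals = np.exp(-0.5 * r2 / self._sr ** 2)
        return vals if np.asarray(points).ndim > 1 else float(vals[0])


def analytic_gaussian_map(center, sigma_ref=0.6) -> DensityMap:
    return _AnalyticGaussianMap(center, sigma_ref)


def sampled_gaussian(center, sigma_ref=0.6, shape=(32, 32, 32),
                     voxel=0.25) -> DensityMap:
    axes = [np.arange(s) * voxel for s in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    r2 = ((X - center[0]) ** 2 + (Y - center[1]) ** 2
          + (Z - center[2]) ** 2)
    return DensityMap(np.exp(-0.5 * r2 / sigma_ref ** 2), voxel, (0, 0, 0))
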