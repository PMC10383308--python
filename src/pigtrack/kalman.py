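"""Constant-velocity Kalman filter on the 8-dimensional box state.

State is ``(cx, cy, gamma, h, vcx, vcy, vgamma, vh)``: box center, aspect
ratio, height and their per-frame rates of change.  Process and measurement
noise scale with the box height — the standard tracking-by-detection
convention, which makes the filter resolution-independent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["KalmanFilter", "CHI2_95_4DOF"]

# chi-square 95% quantile at 4 degrees of freedom (Mahalanobis gate on the
# projected (cx, cy, gamma, h) measurement); scipy.stats.chi2.ppf(0.95, 4).
CHI2_95_4DOF = 9.487729036781154


class KalmanFilter:
    def __init__(self, std_weight_position: float = 1.0 / 20,
                 std_weight_velocity: float = 1.0 / 160,
                 std_gamma_process: float = 2e-2,
                 std_gamma_meas: float = 2e-2):
        # gamma noise is deliberately loose: boxes clipped at the frame edge
        # change aspect ratio fast while an animal enters or leaves, and the
        # filter must follow or association falls apart at the edges.
        ndim, dt = 4, 1.0
        self._F = np.eye(2 * ndim)
        for i in range(ndim):
            self._F[i, ndim + i] = dt
        self._H = np.eye(ndim, 2 * ndim)
        self._std_pos = std_weight_position
        self._std_vel = std_weight_velocity
        self._std_g = std_gamma_process
        self._std_g_meas = std_gamma_meas

    def initiate(self, measurement: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """New (mean, covariance) from an unassociated box measurement."""
        mean = np.zeros(8)
        mean[:4] = measurement
        h = measurement[3]
        std = [2 * self._std_pos * h, 2 * self._std_pos * h, 1e-1, 2 * self._std_pos * h,
               10 * self._std_vel * h, 10 * self._std_vel * h, 1e-1, 10 * self._std_vel * h]
        return mean, np.diag(np.square(std))

    def predict(self, mean: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = mean[3]
        std = [self._std_pos * h, self._std_pos * h, self._std_g, self._std_pos * h,
               self._std_vel * h, self._std_vel * h, self._std_g, self._std_vel * h]
        q = np.diag(np.square(std))
        mean = self._F @ mean
        cov = self._F @ cov @ self._F.T + q
        return mean, cov

    def project(self, mean: np.ndarray, cov: np.ndarray,
                meas_scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        h = mean[3]
        std = [self._std_pos * h, self._std_pos * h, self._std_g_meas, self._std_pos * h]
        r = np.diag(np.square(np.asarray(std) * meas_scale))
        return self._H @ mean, self._H @ cov @ self._H.T + r

    def update(self, mean: np.ndarray, cov: np.ndarray, measurement: np.ndarray,
               meas_scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        pm, pc = self.project(mean, cov, meas_scale)
        k = np.linalg.solve(pc.T, (cov @ self._H.T).T).T  # Kalman gain
        innov = measurement - pm
        new_mean = mean + k @ innov
        new_cov = cov - k @ pc @ k.T
        new_cov = 0.5 * (new_cov + new_cov.T)  # keep symmetric
        return new_mean, new_cov

    def gating_distance(self, mean: np.ndarray, cov: np.ndarray,
                        measurements: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of measurements to the projected state."""
        pm, pc = self.project(mean, cov)
        d = np.atleast_2d(measurements) - pm
        sol = np.linalg.solve(pc, d.T)
        return np.sum(d.T * sol, axis=0)
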