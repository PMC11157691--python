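"""Harmonic interference model and field-correction projectors.

Background magnetic interference across a rigid magnetometer array is
modelled as a sum of gradients of low-order regular solid harmonics.  At
order 1 this is a spatially homogeneous field ``B = [Bx, By, Bz]``: the
interference seen by channel *i* with unit orientation ``rho_i`` is simply
``y_i = B . rho_i``, independent of sensor position.  At order 2 five
linear-gradient terms are appended, built from traceless-symmetric
gradient tensors (so that each basis field is divergence- and curl-free,
as any source-free magnetostatic field must be).

Stacking channel orientations into a matrix ``N`` gives ``Y = N B``; the
field coefficients are recovered with the Moore-Penrose pseudo-inverse,
``B = pinv(N) Y``.  Two projectors follow:

* feedback: ``M pinv(N)`` predicts the interference at the feedback-coil
  orientations ``M`` (a row subset of ``N`` when feeding back through the
  sensors' own on-board coils), giving the field to cancel;
* denoising: ``I - N pinv(N)`` removes the modelled interference from
  recorded data (offline homogeneous field correction, HFC).

Because the array is rigid, both projectors are constant in the array
frame throughout an experiment, however the array moves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import Recording

__all__ = [
    "SensorArray",
    "FieldModel",
    "Projector",
    "build_basis",
    "n_basis_terms",
    "fit_field_model",
    "desired_feedback",
    "apply_hfc_offline",
    "correct_lead_fields",
]

#: The five traceless-symmetric gradient tensors spanning linear field
#: gradients of a source-free field.  Basis field k at position r is
#: ``B_k(r) = G_k @ r`` (zero divergence: trace G_k = 0; zero curl: G_k
#: symmetric).  Units: the coefficient multiplying each term is in T/m.
GRADIENT_TENSORS = np.array(
    [
        [[1.0, 0, 0], [0, -1.0, 0], [0, 0, 0]],   # dBx/dx - dBy/dy
        [[0, 0, 0], [0, 1.0, 0], [0, 0, -1.0]],   # dBy/dy - dBz/dz
        [[0, 1.0, 0], [1.0, 0, 0], [0, 0, 0]],    # dBx/dy = dBy/dx
        [[0, 0, 1.0], [0, 0, 0], [1.0, 0, 0]],    # dBx/dz = dBz/dx
        [[0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]],    # dBy/dz = dBz/dy
    ]
)

#: Relative singular-value cutoff for all pseudo-inverses in this module.
SVD_RCOND = 1e-10


@dataclass
class SensorArray:
    """Rigid geometry of a dual-axis magnetometer array.

    Positions (metres) and unit orientations are expressed in a rigid
    frame fixed to the array (e.g. the scanner-cast frame), so matrices
    built from them are constant under array motion.  Each physical OPM
    contributes two channels: one radial to the head (axis tag ``"Y"``)
    and one tangential (``"Z"``).  Channel ordering is stable and defines
    the row order of every matrix built from the array.

    Parameters
    ----------
    labels : list of str
        Unique channel labels.
    positions : ndarray, shape (n, 3)
        Channel positions in metres.
    orientations : ndarray, shape (n, 3)
        Unit sensitive-axis orientations.
    axes : list of str
        Per-channel axis tag, ``"Y"`` (radial) or ``"Z"`` (tangential).
    feedback : ndarray of bool, shape (n,)
        True where the channel's on-board coil receives feedback.
    frame : str
        Name of the rigid frame (informational).
    """

    labels: list[str]
    positions: np.ndarray
    orientations: np.ndarray
    axes: list[str]
    feedback: np.ndarray
    frame: str = "scanner-cast"

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        self.feedback = np.asarray(self.feedback, dtype=bool)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise ValueError("positions and orientations must be (n, 3)")
        if len(self.axes) != n or self.feedback.shape != (n,):
            raise ValueError("axes and feedback must have one entry per channel")
        bad = [a for a in self.axes if a not in ("Y", "Z")]
        if bad:
            raise ValueError(f"axis tags must be 'Y' or 'Z', got {bad}")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors (|1 - norm| <= 1e-9)")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def feedback_indices(self) -> np.ndarray:
        """Indices of feedback-enabled channels, in array order."""
        return np.flatnonzero(self.feedback)

    # ---------------------------------------------------------------- I/O
    def to_json(self, path) -> None:
        """Write the layout as a JSON sidecar."""
        obj = {
            "frame": self.frame,
            "channels": [
                {
                    "label": self.labels[i],
                    "position_m": self.positions[i].tolist(),
                    "orientation": self.orientations[i].tolist(),
                    "axis": self.axes[i],
                    "feedback": bool(self.feedback[i]),
                }
                for i in range(self.n_channels)
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SensorArray":
        """Read a layout from its JSON sidecar."""
        with open(path) as fh:
            obj = json.load(fh)
        ch = obj["channels"]
        return cls(
            labels=[c["label"] for c in ch],
            positions=np.array([c["position_m"] for c in ch], dtype=float),
            orientations=np.array([c["orientation"] for c in ch], dtype=float),
            axes=[c["axis"] for c in ch],
            feedback=np.array([bool(c.get("feedback", True)) for c in ch]),
            frame=obj.get("frame", "scanner-cast"),
        )

    @classmethod
    def from_tsv(cls, path) -> "SensorArray":
        """Read a layout from a TSV with columns
        label, px, py, pz, ox, oy, oz, axis, feedback."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(
            labels=[str(x) for x in df["label"]],
            positions=df[["px", "py", "pz"]].to_numpy(float),
            orientations=df[["ox", "oy", "oz"]].to_numpy(float),
            axes=[str(a) for a in df["axis"]],
            feedback=df["feedback"].to_numpy(bool),
        )


@dataclass
class FieldModel:
    """Fitted coefficients of the interference model.

    For order 1 the coefficients are the homogeneous field ``[Bx, By, Bz]``
    in tesla; order 2 appends five gradient coefficients in T/m.
    """

    order: int
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = n_basis_terms(self.order)
        if self.coefficients.shape != (expected,):
            raise ValueError(
                f"order {self.order} needs {expected} coefficients, "
                f"got {self.coefficients.shape}"
            )


def n_basis_terms(order: int) -> int:
    """Number of basis terms for a model of the given order (3 or 8)."""
    if order == 1:
        return 3
    if order == 2:
        return 8
    raise ValueError("order must be 1 or 2")


def build_basis(array: SensorArray, order: int = 1) -> np.ndarray:
    """Build the interference basis matrix ``N`` for an array.

    Row *i* of ``N`` contains the response of channel *i* to each basis
    field.  For order 1 this is just the channel orientation (homogeneous
    fields couple through the dot product only, positions are irrelevant).
    For order 2, five columns are appended with the linear-gradient basis
    fields evaluated at the channel positions and projected onto the
    channel orientations.

    Parameters
    ----------
    array : SensorArray
    order : int
        1 (homogeneous) or 2 (homogeneous + linear gradients).

    Returns
    -------
    ndarray, shape (n_channels, 3) or (n_channels, 8)
    """
    terms = n_basis_terms(order)
    if array.n_channels < terms:
        raise ValueError(
            f"order-{order} model needs at least {terms} channels, "
            f"array has {array.n_channels} (rank-deficient)"
        )
    cols = [array.orientations]
    if order == 2:
        # response of channel i to gradient tensor G: rho_i . (G r_i)
        grad = np.einsum("nj,kjl,nl->nk", array.orientations,
                         GRADIENT_TENSORS, array.positions)
        cols.append(grad)
    return np.hstack(cols)


@dataclass
class Projector:
    """Feedback and denoising projectors for a sensor array.

    Attributes
    ----------
    N : ndarray (n_channels, n_terms)
        Interference basis over all recording channels.
    M : ndarray (n_feedback, n_terms)
        Row subset of ``N`` for feedback-enabled channels, in array order.
    pinvN : ndarray (n_terms, n_channels)
        Moore-Penrose pseudo-inverse of ``N`` (SVD, relative cutoff 1e-10).
    feedback_matrix : ndarray (n_feedback, n_channels)
        ``M pinv(N)`` — maps channel readings to the field to feed back.
    denoise_matrix : ndarray (n_channels, n_channels)
        ``I - N pinv(N)`` — removes the modelled interference.
    """

    array: SensorArray
    order: int = 1
    N: np.ndarray = field(init=False)
    M: np.ndarray = field(init=False)
    pinvN: np.ndarray = field(init=False)
    feedback_matrix: np.ndarray = field(init=False)
    denoise_matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.N = build_basis(self.array, self.order)
        self.M = self.N[self.array.feedback]
        self.pinvN = _pinv_reporting(self.N)
        self.feedback_matrix = self.M @ self.pinvN
        self.denoise_matrix = np.eye(self.array.n_channels) - self.N @ self.pinvN

    @property
    def feedback_labels(self) -> list[str]:
        return [self.array.labels[i] for i in self.array.feedback_indices]


def _pinv_reporting(N: np.ndarray) -> np.ndarray:
    """SVD pseudo-inverse with a relative cutoff; warns on dropped modes."""
    u, s, vt = np.linalg.svd(N, full_matrices=False)
    cutoff = SVD_RCOND * s[0] if s.size else 0.0
    keep = s > cutoff
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} singular value(s) below "
            f"{cutoff:.3e} in pseudo-inverse (degenerate array geometry)",
            stacklevel=3,
        )
    sinv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    return (vt.T * sinv) @ u.T


def fit_field_model(N: np.ndarray, y: np.ndarray, order: int | None = None) -> FieldModel:
    """Least-squares fit of the field model to one channel vector.

    Solves ``min_b ||N b - y||`` via the pseudo-inverse: ``b = pinv(N) y``.

    Parameters
    ----------
    N : ndarray (n_channels, n_terms)
        Basis from :func:`build_basis`.
    y : ndarray (n_channels,)
        One sample of per-channel field readings in tesla.  Must not
        contain NaN; saturated samples are the caller's responsibility to
        exclude (by row-masking both ``N`` and ``y``).
    order : int, optional
        Model order recorded on the result; inferred from ``N`` if omitted.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N.shape[0],):
        raise ValueError(f"y has shape {y.shape}, expected ({N.shape[0]},)")
    if np.isnan(y).any():
        raise ValueError("y contains NaN; mask saturated/missing samples first")
    if np.linalg.matrix_rank(N, tol=SVD_RCOND * np.linalg.norm(N, 2)) < N.shape[1]:
        raise ValueError(
            "basis matrix is rank-deficient: the channel orientations/"
            "positions do not span the model space (degenerate geometry, "
            "e.g. coplanar orientations for an order-1 fit)"
        )
    if order is None:
        order = 1 if N.shape[1] == 3 else 2
    return FieldModel(order=order, coefficients=_pinv_reporting(N) @ y)


def desired_feedback(proj: Projector, u: np.ndarray) -> np.ndarray:
    """Field to feed back at each feedback coil: ``M pinv(N) u``.

    ``u`` is the per-channel estimate of the uncorrected background field
    (one sample).  The result follows the feedback-channel ordering of
    ``M`` (array order restricted to feedback-enabled channels).
    """
    u = np.asarray(u, dtype=float)
    if u.shape[0] != proj.N.shape[0]:
        raise ValueError(
            f"u has {u.shape[0]} channels, projector expects {proj.N.shape[0]}"
        )
    return proj.feedback_matrix @ u


def apply_hfc_offline(proj: Projector, data: Recording) -> Recording:
    """Offline homogeneous field correction of a recording.

    Every sample is replaced by ``(I - N pinv(N)) sample``, leaving the
    residual orthogonal to the modelled interference subspace at every
    time point.  The saturation mask is carried through unchanged.
    """
    if data.n_channels != proj.N.shape[0]:
        raise ValueError(
            f"recording has {data.n_channels} channels, "
            f"projector expects {proj.N.shape[0]}"
        )
    return data.copy_with(data=proj.denoise_matrix @ data.data)


def correct_lead_fields(proj: Projector, L: np.ndarray) -> np.ndarray:
    """Apply the denoising projector to forward-model lead fields.

    When recorded data are projected with ``I - N pinv(N)``, the lead
    fields of any forward model used for source analysis must be
    multiplied by the same matrix so that data and model live in the same
    (reduced) space.
    """
    L = np.asarray(L, dtype=float)
    if L.shape[0] != proj.N.shape[0]:
        raise ValueError(
            f"lead fields have {L.shape[0]} rows, projector expects {proj.N.shape[0]}"
        )
    return proj.denoise_matrix @ L
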