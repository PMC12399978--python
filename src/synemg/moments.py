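"""Joint moments from muscle forces and moment arms.

Four degrees of freedom are modelled: arm adduction-abduction, arm
flexion-extension, arm internal-external rotation, elbow flexion-extension
(arm flexion, adduction, internal rotation and elbow flexion positive).
The moment about DOF i is the superposition

    M_i = sum_j F0m_j * (F_CE_j + F_PE_j) * r_ij * cos(alpha_j),

with r_ij the moment arm (m) of muscle j about DOF i.  Each of the ten
modelled muscles crosses a fixed subset of the DOFs with a fixed moment-arm
sign; the table below encodes that anatomy (+1 / -1 / 0 = does not cross).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MUSCLES", "DOFS", "SIGN_TABLE", "sign_matrix",
           "compute_joint_moments", "check_sign_structure"]

MUSCLES = ["BB", "TB", "AD", "MD", "PD", "IF", "TMj", "LD", "PM", "BRD"]
MUSCLE_NAMES = {
    "BB": "biceps brachii", "TB": "triceps brachii", "AD": "anterior deltoid",
    "MD": "middle deltoid", "PD": "posterior deltoid", "IF": "infraspinatus",
    "TMj": "teres major", "LD": "latissimus dorsi", "PM": "pectoralis major",
    "BRD": "brachioradialis",
}
DOFS = ["arm_add_abd", "arm_flex_ext", "arm_int_ext_rot", "elbow_flex_ext"]

# sign of the moment arm of each muscle (column) about each DOF (row);
# 0 marks muscles that do not cross the DOF.
SIGN_TABLE: dict[str, dict[str, int]] = {
    #        add/abd  flex/ext  int/ext rot  elbow
    "BB":  {"arm_add_abd": 0,  "arm_flex_ext": +1, "arm_int_ext_rot": 0,  "elbow_flex_ext": +1},
    "TB":  {"arm_add_abd": +1, "arm_flex_ext": -1, "arm_int_ext_rot": 0,  "elbow_flex_ext": -1},
    "AD":  {"arm_add_abd": -1, "arm_flex_ext": +1, "arm_int_ext_rot": +1, "elbow_flex_ext": 0},
    "MD":  {"arm_add_abd": -1, "arm_flex_ext": 0,  "arm_int_ext_rot": 0,  "elbow_flex_ext": 0},
    "PD":  {"arm_add_abd": -1, "arm_flex_ext": -1, "arm_int_ext_rot": -1, "elbow_flex_ext": 0},
    "IF":  {"arm_add_abd": +1, "arm_flex_ext": -1, "arm_int_ext_rot": -1, "elbow_flex_ext": 0},
    "TMj": {"arm_add_abd": +1, "arm_flex_ext": -1, "arm_int_ext_rot": +1, "elbow_flex_ext": 0},
    "LD":  {"arm_add_abd": +1, "arm_flex_ext": -1, "arm_int_ext_rot": +1, "elbow_flex_ext": 0},
    "PM":  {"arm_add_abd": +1, "arm_flex_ext": +1, "arm_int_ext_rot": +1, "elbow_flex_ext": 0},
    "BRD": {"arm_add_abd": 0,  "arm_flex_ext": 0,  "arm_int_ext_rot": 0,  "elbow_flex_ext": +1},
}


def sign_matrix(muscles=MUSCLES, dofs=DOFS) -> np.ndarray:
    """(n_dofs, n_muscles) matrix of moment-arm signs (+1, -1, 0)."""
    return np.array([[SIGN_TABLE[m][d] for m in muscles] for d in dofs],
                    dtype=float)


def compute_joint_moments(fiber_force_bar: np.ndarray, cos_pen: np.ndarray,
                          arms: np.ndarray, f0m: np.ndarray) -> np.ndarray:
    """Joint moment series from normalized fiber forces.

    Parameters
    ----------
    fiber_force_bar : (n, m) normalized F_CE + F_PE per frame per muscle.
    cos_pen : (n, m) pennation cosines.
    arms : (n, n_dofs, m) moment arms in meters.
    f0m : (m,) maximum isometric forces in newtons.

    Returns (n, n_dofs) moments in N*m.
    """
    fiber_force_bar = np.asarray(fiber_force_bar, dtype=float)
    cos_pen = np.asarray(cos_pen, dtype=float)
    arms = np.asarray(arms, dtype=float)
    f0m = np.asarray(f0m, dtype=float)
    n, m = fiber_force_bar.shape
    if arms.shape[0] != n or arms.shape[2] != m or cos_pen.shape != (n, m):
        raise ValueError("muscle states and moment arms disagree in grid or muscle set")
    force = f0m[None, :] * fiber_force_bar * cos_pen  # (n, m) fiber force along tendon
    return np.einsum("tij,tj->ti", arms, force)


def check_sign_structure(arms: np.ndarray, muscles=MUSCLES, dofs=DOFS,
                         table: dict | None = None) -> list[tuple[str, str, str]]:
    """Check a moment-arm set against the anatomical sign table.

    arms : (n, n_dofs, n_muscles).  Returns a list of violations
    (muscle, dof, description); an empty list means full conformance.
    Muscles that do not cross a DOF must have an identically zero arm there;
    crossing muscles must keep the tabulated sign at every frame.
    """
    arms = np.asarray(arms, dtype=float)
    table = table if table is not None else SIGN_TABLE
    violations = []
    for i, d in enumerate(dofs):
        for j, mu in enumerate(muscles):
            expected = table[mu][d]
            col = arms[:, i, j]
            if expected == 0:
                if np.any(col != 0):
                    violations.append((mu, d, "nonzero arm for a non-crossing muscle"))
            elif np.any(expected * col <= 0):
                violations.append((mu, d, f"sign deviates from {expected:+d}"))
    return violations
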