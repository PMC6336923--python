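"""Flatten the free (unmasked) parameters of a model into a labeled vector.

Symmetric matrices (Q, P0) contribute only their upper triangles; setting
a triangle entry mirrors it.  The ordering is fixed: state A, B, Q, x0,
P0, then per channel bias, C, D, dispersion.
"""

from __future__ import annotations

import numpy as np

from .model import ModelSpec


def free_param_labels(spec: ModelSpec):
    labels, _ = get_free_params(spec)
    return labels


def _matrix_entries(name, M, mask, symmetric=False):
    out = []
    n, m = M.shape
    for i in range(n):
        for j in range(i if symmetric else 0, m):
            if mask[i, j]:
                out.append((f"{name}[{i},{j}]", (i, j)))
    return out


def get_free_params(spec: ModelSpec):
    """Return (labels, values) for every free parameter of the spec."""
    labels, values = [], []
    st = spec.state
    for name, M, mask, sym in (("A", st.A, st.mask_A, False),
                               ("B", st.B, st.mask_B, False),
                               ("Q", st.Q, st.mask_Q, True)):
        for lab, (i, j) in _matrix_entries(name, M, mask, sym):
            labels.append(lab)
            values.append(M[i, j])
    for i in range(st.d):
        if st.mask_x0[i]:
            labels.append(f"x0[{i}]")
            values.append(st.x0[i])
    for lab, (i, j) in _matrix_entries("P0", st.P0, st.mask_P0, True):
        labels.append(lab)
        values.append(st.P0[i, j])
    for ch in spec.channels:
        pre = f"ch.{ch.name}"
        if ch.mask_bias:
            labels.append(f"{pre}.bias")
            values.append(ch.bias)
        for i in range(ch.C.shape[0]):
            if ch.mask_C[i]:
                labels.append(f"{pre}.C[{i}]")
                values.append(ch.C[i])
        for i in range(ch.D.shape[0]):
            if ch.mask_D[i]:
                labels.append(f"{pre}.D[{i}]")
                values.append(ch.D[i])
        if ch.has_dispersion and ch.mask_dispersion:
            labels.append(f"{pre}.dispersion")
            values.append(ch.dispersion)
    return labels, np.array(values, dtype=float)


def set_free_params(spec: ModelSpec, values) -> ModelSpec:
    """Return a copy of the spec with its free parameters set to ``values``."""
    values = np.asarray(values, dtype=float)
    out = spec.copy()
    st = out.state
    pos = 0

    def take():
        nonlocal pos
        v = values[pos]
        pos += 1
        return float(v)

    for M, mask, sym in ((st.A, st.mask_A, False), (st.B, st.mask_B, False),
                         (st.Q, st.mask_Q, True)):
        for _, (i, j) in _matrix_entries("", M, mask, sym):
            M[i, j] = take()
            if sym:
                M[j, i] = M[i, j]
    for i in range(st.d):
        if st.mask_x0[i]:
            st.x0[i] = take()
    for _, (i, j) in _matrix_entries("", st.P0, st.mask_P0, True):
        st.P0[i, j] = take()
        st.P0[j, i] = st.P0[i, j]
    for ch in out.channels:
        if ch.mask_bias:
            ch.bias = take()
        for i in range(ch.C.shape[0]):
            if ch.mask_C[i]:
                ch.C[i] = take()
        for i in range(ch.D.shape[0]):
            if ch.mask_D[i]:
                ch.D[i] = take()
        if ch.has_dispersion and ch.mask_dispersion:
            ch.dispersion = take()
    if pos != values.shape[0]:
        raise ValueError(f"expected {pos} free parameters, got {values.shape[0]}")
    return out
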