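"""Hot loops of the collapsed variational E-step (numba-compiled).

One sweep visits patients in index order; within a patient: token records
(type, then feature order), then observed lab records grouped by lab, then
unobserved labs.  Every record update removes its own current contribution
from the cached sufficient statistics (clipped at zero against drift),
computes the zero-order collapsed update, renormalizes in linear space, and
writes the new contribution back (Gauss-Seidel).
"""

import numpy as np
from numba import njit

__all__ = ["sweep_kernel"]


@njit(cache=True)
def sweep_kernel(
    patients,
    tok_start, tok_type, tok_col, tok_cnt, gamma,
    obs_start, obs_lab, obs_row, obs_y, lam,
    mis_start, mis_lab, pi,
    n_jk, m_jk, n_wk, n_tk, m_vk, p, q,
    alpha, beta_flat, beta_sum, zeta_flat, zeta_sum, lab_off, lab_V, a, b,
):
    K = n_jk.shape[1]
    Vmax = pi.shape[2] if pi.shape[0] > 0 else 1
    tmp = np.empty(K)
    excl_j = np.empty(K)
    excl_w = np.empty(K)
    excl_t = np.empty(K)
    mass = np.empty(K)
    tmp2 = np.empty((K, Vmax))

    for jj in range(patients.shape[0]):
        j = patients[jj]

        # ---- token records: gamma updates -------------------------------
        for r in range(tok_start[j], tok_start[j + 1]):
            t = tok_type[r]
            col = tok_col[r]
            c = float(tok_cnt[r])
            tot = 0.0
            for k in range(K):
                old = gamma[r, k] * c
                nj = n_jk[j, k] - old
                if nj < 0.0:
                    nj = 0.0
                nw = n_wk[col, k] - old
                if nw < 0.0:
                    nw = 0.0
                nt = n_tk[t, k] - old
                if nt < 0.0:
                    nt = 0.0
                excl_j[k] = nj
                excl_w[k] = nw
                excl_t[k] = nt
                val = (alpha[k] + nj + m_jk[j, k]) * (beta_flat[col] + nw) / (beta_sum[t] + nt)
                tmp[k] = val
                tot += val
            for k in range(K):
                new = tmp[k] / tot if tot > 0.0 else 1.0 / K
                n_jk[j, k] = excl_j[k] + c * new
                n_wk[col, k] = excl_w[k] + c * new
                n_tk[t, k] = excl_t[k] + c * new
                gamma[r, k] = new

        # ---- observed lab records: lambda updates, grouped by lab -------
        r = obs_start[j]
        end = obs_start[j + 1]
        while r < end:
            l = obs_lab[r]
            r2 = r
            while r2 < end and obs_lab[r2] == l:
                r2 += 1
            off = lab_off[l]
            V = lab_V[l]
            # current total mass of this (lab, patient) pair over its states
            for k in range(K):
                mass[k] = 0.0
            for rr in range(r, r2):
                y = float(obs_y[rr])
                for k in range(K):
                    mass[k] += y * lam[rr, k]
            for rr in range(r, r2):
                y = float(obs_y[rr])
                row = obs_row[rr]
                tot = 0.0
                for k in range(K):
                    old = y * lam[rr, k]
                    mj = m_jk[j, k] - mass[k]
                    if mj < 0.0:
                        mj = 0.0
                    mv = m_vk[row, k] - old
                    if mv < 0.0:
                        mv = 0.0
                    msum = 0.0
                    for v in range(V):
                        msum += m_vk[off + v, k]
                    msum -= old
                    if msum < 0.0:
                        msum = 0.0
                    pe = p[l, k] - mass[k]
                    if pe < 0.0:
                        pe = 0.0
                    val = (
                        (alpha[k] + n_jk[j, k] + mj)
                        * (zeta_flat[row] + mv) / (zeta_sum[l] + msum)
                        * (a[l] + pe) / (a[l] + pe + b[l] + q[l, k])
                    )
                    tmp[k] = val
                    tot += val
                for k in range(K):
                    new = tmp[k] / tot if tot > 0.0 else 1.0 / K
                    d = y * new - y * lam[rr, k]
                    m_vk[row, k] += d
                    p[l, k] += d
                    m_jk[j, k] += d
                    mass[k] += d
                    lam[rr, k] = new
            r = r2

        # ---- unobserved labs: joint (topic, state) pi updates -----------
        for u in range(mis_start[j], mis_start[j + 1]):
            l = mis_lab[u]
            off = lab_off[l]
            V = lab_V[l]
            for k in range(K):
                s = 0.0
                for v in range(V):
                    s += pi[u, k, v]
                mass[k] = s
            tot = 0.0
            for k in range(K):
                mj = m_jk[j, k] - mass[k]
                if mj < 0.0:
                    mj = 0.0
                qe = q[l, k] - mass[k]
                if qe < 0.0:
                    qe = 0.0
                base = (alpha[k] + n_jk[j, k] + mj) * (b[l] + qe) / (a[l] + p[l, k] + b[l] + qe)
                msum = 0.0
                for v in range(V):
                    msum += m_vk[off + v, k]
                for v in range(V):
                    old = pi[u, k, v]
                    mv = m_vk[off + v, k] - old
                    if mv < 0.0:
                        mv = 0.0
                    ms = msum - old
                    if ms < 0.0:
                        ms = 0.0
                    val = base * (zeta_flat[off + v] + mv) / (zeta_sum[l] + ms)
                    tmp2[k, v] = val
                    tot += val
            for k in range(K):
                dk = 0.0
                for v in range(V):
                    new = tmp2[k, v] / tot if tot > 0.0 else 1.0 / (K * V)
                    d = new - pi[u, k, v]
                    m_vk[off + v, k] += d
                    dk += d
                    pi[u, k, v] = new
                q[l, k] += dk
                m_jk[j, k] += dk
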