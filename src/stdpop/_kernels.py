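"""Numba kernels: LIF co-simulation with event-driven plasticity.

Two families of kernels, one per rule group:

``*_frozen``
    Weights are held fixed; candidate potentiation and depression are
    accumulated per synapse without being applied.  Used for drift
    estimation.  The suppression kernel accumulates potentiation for a whole
    batch of ``tau_plus`` values in one pass (the nearest-neighbor pairing
    structure and the efficacies do not depend on ``tau_plus``); the NMDAR
    kernel accumulates the thresholded messenger sums so that any
    ``(A_+, A_-)`` combination can be evaluated afterwards by linearity.

``*_evolve``
    Weights evolve under the rule and a bounds policy (0 = hard clipping,
    1 = soft bounds: potentiation scaled by ``1 - w/w_max``, depression by
    ``w/w_max``).  Group-mean trajectories are recorded on a fixed stride.

Conventions shared by all kernels: presynaptic spikes are binned to the dt
grid and processed at the bin start (transmission first, then the rule's
presynaptic plasticity step); the membrane is advanced with its exact
exponential update; a postsynaptic spike is emitted mid-bin, after the bin's
presynaptic events.  Per-synapse traces decay lazily between the events that
touch them.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SENTINEL = -1.0e18


@njit(cache=True)
def _lif_consts(dt, tau_m, tau_s):
    a = math.exp(-dt / tau_m)
    ds = math.exp(-dt / tau_s)
    b = tau_s / (tau_m - tau_s) * (a - ds)
    return a, ds, b


# ---------------------------------------------------------------------------
# frozen-weight accumulators
#
# With frozen weights the postsynaptic train does not depend on the candidate
# plasticity, so drift estimation is two-phase: the LIF loop produces the
# post train once, and these accumulators replay the merged pre/post event
# stream.  Presynaptic events are sorted by time; a pre and a post event
# never collide (posts sit mid-bin).  The split also allows an exact
# variance-reduction control: replaying the same pre trains against a
# time-shifted copy of the post train isolates the pre-post-correlation
# (w-dependent) part of the drift.


@njit(cache=True)
def accum_pair_triplet(
    pre_times, pre_syn, post_times, n_ex,
    a_plus, a_minus, tau_plus, tau_minus,
    a_pre, a_post, tau_pre, tau_post,
):
    """The pair rule is the special case a_pre = a_post = 0."""
    r1 = np.zeros(n_ex)
    mpre = np.zeros(n_ex)
    tlast = np.zeros(n_ex)
    tpre_last = np.zeros(n_ex)
    pot = np.zeros(n_ex)
    dep = np.zeros(n_ex)
    o1 = 0.0
    mpost = 0.0
    t_glob = 0.0
    p = 0
    q = 0
    n_pre = pre_times.size
    n_post = post_times.size
    while p < n_pre or q < n_post:
        if q >= n_post or (p < n_pre and pre_times[p] < post_times[q]):
            t = pre_times[p]
            i = pre_syn[p]
            o1 *= math.exp(-(t - t_glob) / tau_minus)
            mpost *= math.exp(-(t - t_glob) / tau_post)
            t_glob = t
            r1[i] *= math.exp(-(t - tlast[i]) / tau_plus)
            tlast[i] = t
            mpre[i] *= math.exp(-(t - tpre_last[i]) / tau_pre)
            tpre_last[i] = t
            dep[i] += (a_minus + mpre[i]) * o1
            mpre[i] += a_pre
            r1[i] += 1.0
            p += 1
        else:
            t = post_times[q]
            o1 *= math.exp(-(t - t_glob) / tau_minus)
            mpost *= math.exp(-(t - t_glob) / tau_post)
            t_glob = t
            amp = a_plus + mpost  # M_post read before its own increment
            for i in range(n_ex):
                r1[i] *= math.exp(-(t - tlast[i]) / tau_plus)
                tlast[i] = t
                pot[i] += amp * r1[i]
            o1 += 1.0
            mpost += a_post
            q += 1
    return pot, dep


@njit(cache=True)
def accum_suppression(
    pre_times, pre_syn, post_times, n_ex,
    a_plus, a_minus, tau_plus_batch, tau_minus,
    tau_pre, tau_post,
):
    """All-to-all pairing with per-spike efficacy suppression.

    Every pre/post pair contributes, each spike weighted by its efficacy
    ``1 - exp(-gap/tau)`` w.r.t. its same-type predecessor; implemented with
    efficacy-weighted exponential traces.  ``r1[j, i]`` is the potentiation
    trace of synapse i for the j-th tau_plus in the batch; ``o1`` the shared
    efficacy-weighted post trace for depression."""
    n_tau = tau_plus_batch.size
    tpre_last = np.full(n_ex, _SENTINEL)
    tlast = np.zeros(n_ex)
    r1 = np.zeros((n_tau, n_ex))
    pot = np.zeros((n_tau, n_ex))
    dep = np.zeros(n_ex)
    tpost_last = _SENTINEL
    o1 = 0.0
    t_glob = 0.0
    p = 0
    q = 0
    n_pre = pre_times.size
    n_post = post_times.size
    while p < n_pre or q < n_post:
        if q >= n_post or (p < n_pre and pre_times[p] < post_times[q]):
            t = pre_times[p]
            i = pre_syn[p]
            if tpre_last[i] > _SENTINEL / 2:
                effnew = 1.0 - math.exp(-(t - tpre_last[i]) / tau_pre)
            else:
                effnew = 1.0
            o1g = o1 * math.exp(-(t - t_glob) / tau_minus)
            dep[i] += effnew * a_minus * o1g
            el = t - tlast[i]
            tlast[i] = t
            for j in range(n_tau):
                r1[j, i] = r1[j, i] * math.exp(-el / tau_plus_batch[j]) + effnew
            tpre_last[i] = t
            p += 1
        else:
            t = post_times[q]
            if tpost_last > _SENTINEL / 2:
                effnew = 1.0 - math.exp(-(t - tpost_last) / tau_post)
            else:
                effnew = 1.0
            for i in range(n_ex):
                el = t - tlast[i]
                tlast[i] = t
                for j in range(n_tau):
                    r1[j, i] *= math.exp(-el / tau_plus_batch[j])
                    pot[j, i] += a_plus * effnew * r1[j, i]
            o1 = o1 * math.exp(-(t - t_glob) / tau_minus) + effnew
            t_glob = t
            tpost_last = t
            q += 1
    return pot, dep


@njit(cache=True)
def accum_nmdar(
    pre_times, pre_syn, post_times, n_ex,
    a_f_up, a_f_dn, a_m_up, a_m_dn,
    tau_f_up, tau_f_dn, tau_m_up, tau_m_dn,
    theta_up, theta_dn,
):
    """Accumulates ``P[i] = sum_post [M_up - theta_up]_+`` and
    ``D[i] = sum_pre [M_dn - theta_dn]_+`` (amplitude-free), plus the raw
    messenger sums ``Mup_raw``/``Mdn_raw`` at the same events (diagnostics
    for the size of the threshold-fluctuation effect)."""
    fup = np.zeros(n_ex)
    fdn = np.zeros(n_ex)
    mup = np.zeros(n_ex)
    mdn = np.zeros(n_ex)
    tlast = np.zeros(n_ex)
    P = np.zeros(n_ex)
    D = np.zeros(n_ex)
    Mup_raw = np.zeros(n_ex)
    Mdn_raw = np.zeros(n_ex)
    p = 0
    q = 0
    n_pre = pre_times.size
    n_post = post_times.size
    while p < n_pre or q < n_post:
        if q >= n_post or (p < n_pre and pre_times[p] < post_times[q]):
            t = pre_times[p]
            i = pre_syn[p]
            el = t - tlast[i]
            tlast[i] = t
            fup[i] *= math.exp(-el / tau_f_up)
            fdn[i] *= math.exp(-el / tau_f_dn)
            mup[i] *= math.exp(-el / tau_m_up)
            mdn[i] *= math.exp(-el / tau_m_dn)
            fup[i] += a_f_up * (1.0 - fup[i] - fdn[i])
            mdn[i] += a_m_dn * fdn[i] * (1.0 - mdn[i])
            Mdn_raw[i] += mdn[i]
            ex = mdn[i] - theta_dn
            if ex > 0.0:
                D[i] += ex
            p += 1
        else:
            t = post_times[q]
            for i in range(n_ex):
                el = t - tlast[i]
                tlast[i] = t
                fup[i] *= math.exp(-el / tau_f_up)
                fdn[i] *= math.exp(-el / tau_f_dn)
                mup[i] *= math.exp(-el / tau_m_up)
                mdn[i] *= math.exp(-el / tau_m_dn)
                mup[i] += a_m_up * fup[i] * (1.0 - mup[i])
                fdn[i] += a_f_dn * (1.0 - fup[i] - fdn[i])
                Mup_raw[i] += mup[i]
                ex = mup[i] - theta_up
                if ex > 0.0:
                    P[i] += ex
            q += 1
    return P, D, Mup_raw, Mdn_raw


# ---------------------------------------------------------------------------
# evolution kernels (plasticity applied, weights bounded)


@njit(cache=True, inline="always")
def _apply_pot(w, amount, bounds_kind, w_max):
    if bounds_kind == 1:
        amount *= 1.0 - w / w_max
    w += amount
    if w > w_max:
        w = w_max
    return w


@njit(cache=True, inline="always")
def _apply_dep(w, amount, bounds_kind, w_max):
    if bounds_kind == 1:
        amount *= w / w_max
    w -= amount
    if w < 0.0:
        w = 0.0
    return w


@njit(cache=True)
def evolve_pair_triplet(
    ex_steps, ex_syn, inc_in, w, dt, n_steps,
    tau_m, tau_s, v_th, v_r,
    a_plus, a_minus, tau_plus, tau_minus,
    a_pre, a_post, tau_pre, tau_post,
    bounds_kind, w_max, rec_stride, corr_mask,
):
    n_ex = w.size
    a, ds, b = _lif_consts(dt, tau_m, tau_s)
    r1 = np.zeros(n_ex)
    mpre = np.zeros(n_ex)
    tlast = np.zeros(n_ex)
    tpre_last = np.zeros(n_ex)
    o1 = 0.0
    mpost = 0.0
    t_glob = 0.0
    v = v_r
    i_ex = 0.0
    i_in = 0.0
    p = 0
    nsp = ex_steps.size
    n_rec = n_steps // rec_stride
    traj = np.empty((n_rec, 3))
    n_post = 0
    n_corr = max(corr_mask.sum(), 1)
    n_unc = max(n_ex - corr_mask.sum(), 1)
    for k in range(n_steps):
        t_bin = k * dt
        while p < nsp and ex_steps[p] == k:
            i = ex_syn[p]
            i_ex += w[i]
            o1 *= math.exp(-(t_bin - t_glob) / tau_minus)
            mpost *= math.exp(-(t_bin - t_glob) / tau_post)
            t_glob = t_bin
            r1[i] *= math.exp(-(t_bin - tlast[i]) / tau_plus)
            tlast[i] = t_bin
            mpre[i] *= math.exp(-(t_bin - tpre_last[i]) / tau_pre)
            tpre_last[i] = t_bin
            w[i] = _apply_dep(w[i], (a_minus + mpre[i]) * o1, bounds_kind, w_max)
            mpre[i] += a_pre
            r1[i] += 1.0
            p += 1
        i_ex += 0.0
        i_in += inc_in[k]
        v = v_r + (v - v_r) * a + (i_ex - i_in) * b
        i_ex *= ds
        i_in *= ds
        if v >= v_th:
            v = v_r
            t = t_bin + 0.5 * dt
            o1 *= math.exp(-(t - t_glob) / tau_minus)
            mpost *= math.exp(-(t - t_glob) / tau_post)
            t_glob = t
            amp = a_plus + mpost
            for i in range(n_ex):
                r1[i] *= math.exp(-(t - tlast[i]) / tau_plus)
                tlast[i] = t
                w[i] = _apply_pot(w[i], amp * r1[i], bounds_kind, w_max)
            o1 += 1.0
            mpost += a_post
            n_post += 1
        if (k + 1) % rec_stride == 0:
            idx = (k + 1) // rec_stride - 1
            s_all = 0.0
            s_c = 0.0
            for i in range(n_ex):
                s_all += w[i]
                if corr_mask[i]:
                    s_c += w[i]
            traj[idx, 0] = s_all / n_ex
            traj[idx, 1] = s_c / n_corr
            traj[idx, 2] = (s_all - s_c) / n_unc
    return traj, n_post


@njit(cache=True)
def evolve_suppression(
    ex_steps, ex_syn, inc_in, w, dt, n_steps,
    tau_m, tau_s, v_th, v_r,
    a_plus, a_minus, tau_plus, tau_minus,
    tau_pre, tau_post,
    bounds_kind, w_max, rec_stride, corr_mask,
):
    n_ex = w.size
    a, ds, b = _lif_consts(dt, tau_m, tau_s)
    tpre_last = np.full(n_ex, _SENTINEL)
    r1 = np.zeros(n_ex)          # efficacy-weighted pre trace, tau_plus
    tlast = np.zeros(n_ex)
    tpost_last = _SENTINEL
    o1 = 0.0                     # efficacy-weighted post trace, tau_minus
    t_glob = 0.0
    v = v_r
    i_ex = 0.0
    i_in = 0.0
    p = 0
    nsp = ex_steps.size
    n_rec = n_steps // rec_stride
    traj = np.empty((n_rec, 3))
    n_post = 0
    n_corr = max(corr_mask.sum(), 1)
    n_unc = max(n_ex - corr_mask.sum(), 1)
    for k in range(n_steps):
        t_bin = k * dt
        while p < nsp and ex_steps[p] == k:
            i = ex_syn[p]
            i_ex += w[i]
            if tpre_last[i] > _SENTINEL / 2:
                effnew = 1.0 - math.exp(-(t_bin - tpre_last[i]) / tau_pre)
            else:
                effnew = 1.0
            o1g = o1 * math.exp(-(t_bin - t_glob) / tau_minus)
            w[i] = _apply_dep(w[i], effnew * a_minus * o1g, bounds_kind, w_max)
            r1[i] = r1[i] * math.exp(-(t_bin - tlast[i]) / tau_plus) + effnew
            tlast[i] = t_bin
            tpre_last[i] = t_bin
            p += 1
        i_in += inc_in[k]
        v = v_r + (v - v_r) * a + (i_ex - i_in) * b
        i_ex *= ds
        i_in *= ds
        if v >= v_th:
            v = v_r
            t = t_bin + 0.5 * dt
            if tpost_last > _SENTINEL / 2:
                effnew = 1.0 - math.exp(-(t - tpost_last) / tau_post)
            else:
                effnew = 1.0
            for i in range(n_ex):
                r1[i] *= math.exp(-(t - tlast[i]) / tau_plus)
                tlast[i] = t
                w[i] = _apply_pot(w[i], a_plus * effnew * r1[i], bounds_kind, w_max)
            o1 = o1 * math.exp(-(t - t_glob) / tau_minus) + effnew
            t_glob = t
            tpost_last = t
            n_post += 1
        if (k + 1) % rec_stride == 0:
            idx = (k + 1) // rec_stride - 1
            s_all = 0.0
            s_c = 0.0
            for i in range(n_ex):
                s_all += w[i]
                if corr_mask[i]:
                    s_c += w[i]
            traj[idx, 0] = s_all / n_ex
            traj[idx, 1] = s_c / n_corr
            traj[idx, 2] = (s_all - s_c) / n_unc
    return traj, n_post


@njit(cache=True)
def evolve_suppression_nn(
    ex_steps, ex_syn, inc_in, w, dt, n_steps,
    tau_m, tau_s, v_th, v_r,
    a_plus, a_minus, tau_plus, tau_minus,
    tau_pre, tau_post,
    bounds_kind, w_max, rec_stride, corr_mask,
):
    """Strict nearest-neighbor variant: each pre spike pairs only with the
    most recent post spike and vice versa."""
    n_ex = w.size
    a, ds, b = _lif_consts(dt, tau_m, tau_s)
    tpre_last = np.full(n_ex, _SENTINEL)
    effpre = np.ones(n_ex)
    tpost_last = _SENTINEL
    effpost = 1.0
    v = v_r
    i_ex = 0.0
    i_in = 0.0
    p = 0
    nsp = ex_steps.size
    n_rec = n_steps // rec_stride
    traj = np.empty((n_rec, 3))
    n_post = 0
    n_corr = max(corr_mask.sum(), 1)
    n_unc = max(n_ex - corr_mask.sum(), 1)
    for k in range(n_steps):
        t_bin = k * dt
        while p < nsp and ex_steps[p] == k:
            i = ex_syn[p]
            i_ex += w[i]
            if tpre_last[i] > _SENTINEL / 2:
                effnew = 1.0 - math.exp(-(t_bin - tpre_last[i]) / tau_pre)
            else:
                effnew = 1.0
            if tpost_last > _SENTINEL / 2:
                amount = (
                    effnew * effpost * a_minus
                    * math.exp((tpost_last - t_bin) / tau_minus)
                )
                w[i] = _apply_dep(w[i], amount, bounds_kind, w_max)
            effpre[i] = effnew
            tpre_last[i] = t_bin
            p += 1
        i_in += inc_in[k]
        v = v_r + (v - v_r) * a + (i_ex - i_in) * b
        i_ex *= ds
        i_in *= ds
        if v >= v_th:
            v = v_r
            t = t_bin + 0.5 * dt
            if tpost_last > _SENTINEL / 2:
                effnew = 1.0 - math.exp(-(t - tpost_last) / tau_post)
            else:
                effnew = 1.0
            for i in range(n_ex):
                if tpre_last[i] > _SENTINEL / 2:
                    amount = (
                        effpre[i] * effnew * a_plus
                        * math.exp(-(t - tpre_last[i]) / tau_plus)
                    )
                    w[i] = _apply_pot(w[i], amount, bounds_kind, w_max)
            effpost = effnew
            tpost_last = t
            n_post += 1
        if (k + 1) % rec_stride == 0:
            idx = (k + 1) // rec_stride - 1
            s_all = 0.0
            s_c = 0.0
            for i in range(n_ex):
                s_all += w[i]
                if corr_mask[i]:
                    s_c += w[i]
            traj[idx, 0] = s_all / n_ex
            traj[idx, 1] = s_c / n_corr
            traj[idx, 2] = (s_all - s_c) / n_unc
    return traj, n_post


@njit(cache=True)
def evolve_nmdar(
    ex_steps, ex_syn, inc_in, w, dt, n_steps,
    tau_m, tau_s, v_th, v_r,
    a_plus, a_minus,
    a_f_up, a_f_dn, a_m_up, a_m_dn,
    tau_f_up, tau_f_dn, tau_m_up, tau_m_dn,
    theta_up, theta_dn,
    bounds_kind, w_max, rec_stride, corr_mask,
):
    n_ex = w.size
    a, ds, b = _lif_consts(dt, tau_m, tau_s)
    fup = np.zeros(n_ex)
    fdn = np.zeros(n_ex)
    mup = np.zeros(n_ex)
    mdn = np.zeros(n_ex)
    tlast = np.zeros(n_ex)
    v = v_r
    i_ex = 0.0
    i_in = 0.0
    p = 0
    nsp = ex_steps.size
    n_rec = n_steps // rec_stride
    traj = np.empty((n_rec, 3))
    n_post = 0
    n_corr = max(corr_mask.sum(), 1)
    n_unc = max(n_ex - corr_mask.sum(), 1)
    for k in range(n_steps):
        t_bin = k * dt
        while p < nsp and ex_steps[p] == k:
            i = ex_syn[p]
            i_ex += w[i]
            el = t_bin - tlast[i]
            tlast[i] = t_bin
            fup[i] *= math.exp(-el / tau_f_up)
            fdn[i] *= math.exp(-el / tau_f_dn)
            mup[i] *= math.exp(-el / tau_m_up)
            mdn[i] *= math.exp(-el / tau_m_dn)
            fup[i] += a_f_up * (1.0 - fup[i] - fdn[i])
            mdn[i] += a_m_dn * fdn[i] * (1.0 - mdn[i])
            ex = mdn[i] - theta_dn
            if ex > 0.0:
                w[i] = _apply_dep(w[i], a_minus * ex, bounds_kind, w_max)
            p += 1
        i_in += inc_in[k]
        v = v_r + (v - v_r) * a + (i_ex - i_in) * b
        i_ex *= ds
        i_in *= ds
        if v >= v_th:
            v = v_r
            t = t_bin + 0.5 * dt
            for i in range(n_ex):
                el = t - tlast[i]
                tlast[i] = t
                fup[i] *= math.exp(-el / tau_f_up)
                fdn[i] *= math.exp(-el / tau_f_dn)
                mup[i] *= math.exp(-el / tau_m_up)
                mdn[i] *= math.exp(-el / tau_m_dn)
                mup[i] += a_m_up * fup[i] * (1.0 - mup[i])
                fdn[i] += a_f_dn * (1.0 - fup[i] - fdn[i])
                ex = mup[i] - theta_up
                if ex > 0.0:
                    w[i] = _apply_pot(w[i], a_plus * ex, bounds_kind, w_max)
            n_post += 1
        if (k + 1) % rec_stride == 0:
            idx = (k + 1) // rec_stride - 1
            s_all = 0.0
            s_c = 0.0
            for i in range(n_ex):
                s_all += w[i]
                if corr_mask[i]:
                    s_c += w[i]
            traj[idx, 0] = s_all / n_ex
            traj[idx, 1] = s_c / n_corr
            traj[idx, 2] = (s_all - s_c) / n_unc
    return traj, n_post
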