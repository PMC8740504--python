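"""Independent, deliberately literal implementations used as test oracles.

Everything here is written as plain loops transcribing the estimator
definitions term by term, sharing no code with the package's engine, so that
agreement between the two is a meaningful check.
"""

import numpy as np

from refsurv.ratetable import expected_hazard_path


def _event_times(times, events):
    return sorted(set(t for t, e in zip(times, events) if e == 1))


def literal_series(subjects, paths_exp=None, paths_ref=None, wB=None,
                   include_pop=True, ratio_weights=True):
    """Term-by-term transcription of the weighted estimator displays.

    At each unique event time s: weights w_i(s) = wB_i * S**_i(s)/S*_i(s),
    expected increments accrued over (previous event time, s] for subjects at
    risk at s; returns every cumulative quantity plus the literal crude
    probability integrals sum S_R(u-) dLambda(u) and sum S_R(u-) dH**(u).
    """
    times = [s.time for s in subjects]
    events = [s.event for s in subjects]
    n = len(subjects)
    if wB is None:
        wB = [1.0] * n
    ev = _event_times(times, events)

    Lam, Hpop, H_R, S_R = [], [], [], []
    F_C, F_O = [], []
    var_haz = []
    cum_lam = cum_pop = 0.0
    fc = fo = 0.0
    cum_var = 0.0
    prev = 0.0
    for s_t in ev:
        num_l = num_o = den = v = 0.0
        for i in range(n):
            if times[i] >= s_t:  # Y_i(s) = 1
                if paths_exp is not None:
                    Hs = float(paths_exp[i].cumhaz(s_t))
                    dHs = Hs - float(paths_exp[i].cumhaz(prev))
                else:
                    Hs, dHs = 0.0, 0.0
                if paths_ref is not None:
                    Hr = float(paths_ref[i].cumhaz(s_t))
                    dHr = Hr - float(paths_ref[i].cumhaz(prev))
                else:
                    Hr, dHr = 0.0, 0.0
                if ratio_weights:
                    w = wB[i] * np.exp(Hs - Hr)
                else:
                    w = wB[i]
                dN = 1.0 if (events[i] == 1 and times[i] == s_t) else 0.0
                num_l += w * (dN - dHs)
                num_o += w * dHr
                den += w
                v += (w * dN) ** 2 if dN else 0.0
        d_lam = num_l / den
        d_pop = (num_o / den) if include_pop else 0.0
        s_prev = np.exp(-(cum_lam + cum_pop))
        cum_lam += d_lam
        cum_pop += d_pop
        s_now = np.exp(-(cum_lam + cum_pop))
        fc += s_prev * d_lam
        fo += s_prev * d_pop
        cum_var += v / den**2
        Lam.append(cum_lam)
        Hpop.append(cum_pop)
        H_R.append(cum_lam + cum_pop)
        S_R.append(s_now)
        F_C.append(fc)
        F_O.append(fo)
        var_haz.append(cum_var)
        prev = s_t
    return {
        "event_times": np.array(ev),
        "Lambda_R": np.array(Lam),
        "H_R_pop": np.array(Hpop),
        "H_R": np.array(H_R),
        "S_R": np.array(S_R),
        "F_C_literal": np.array(F_C),
        "F_O_literal": np.array(F_O),
        "var_cumhaz": np.array(var_haz),
    }


def _cumhaz_at_event_times(subjects, table, ev):
    """Per subject, H*(s) tabulated at every event time (and at 0)."""
    horizon = max(s.time for s in subjects) + 1e-9
    grid = np.concatenate([[0.0], np.asarray(ev)])
    out = []
    for s in subjects:
        path = expected_hazard_path(s, table, horizon)
        out.append(np.interp(grid, path.breakpoints, path.cumulative))
    return out  # out[i][k+1] = H*_i(ev[k]), out[i][0] = 0


def pohar_perme_net_cumhaz(subjects, expected_table):
    """Pohar Perme net cumulative hazard with 1/S* weights, literal sums."""
    times = [s.time for s in subjects]
    events = [s.event for s in subjects]
    ev = _event_times(times, events)
    H = _cumhaz_at_event_times(subjects, expected_table, ev)
    out, cum = [], 0.0
    for k, s_t in enumerate(ev):
        num = den = 0.0
        for i in range(len(subjects)):
            if times[i] >= s_t:
                w = 1.0 / float(np.exp(-H[i][k + 1]))
                dH = H[i][k + 1] - H[i][k]
                dN = 1.0 if (events[i] == 1 and times[i] == s_t) else 0.0
                num += w * (dN - dH)
                den += w
        cum += num / den
        out.append(cum)
    return np.array(ev), np.array(out)


def ederer2_net_cumhaz(subjects, expected_table):
    """Ederer II net cumulative hazard (unit weights), literal sums."""
    times = [s.time for s in subjects]
    events = [s.event for s in subjects]
    ev = _event_times(times, events)
    H = _cumhaz_at_event_times(subjects, expected_table, ev)
    out, cum = [], 0.0
    for k, s_t in enumerate(ev):
        num = den = 0.0
        for i in range(len(subjects)):
            if times[i] >= s_t:
                dH = H[i][k + 1] - H[i][k]
                dN = 1.0 if (events[i] == 1 and times[i] == s_t) else 0.0
                num += dN - dH
                den += 1.0
        cum += num / den
        out.append(cum)
    return np.array(ev), np.array(out)
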