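"""The ten concentration-response model forms and their evaluation.

Forms follow the ToxCast curve-fitting conventions (tcplfit2 family);
``x`` is concentration in µM (> 0) and the response is zero-centered
fold-change:

========== ======================================== ==================
model      f(x)                                     parameters
========== ======================================== ==================
constant   0                                        (none)
linear     a·x                                      a
quadratic  a·(x/b + (x/b)²)                         a, b
power      a·x^p                                    a, p
hill       tp / (1 + (ga/x)^p)                      tp, ga, p
gain_loss  tp / [(1 + (ga/x)^p)(1 + (x/la)^q)]      tp, ga, p, la, q
exp2       a·(e^(x/b) − 1)                          a, b
exp3       a·(e^((x/b)^p) − 1)                      a, b, p
exp4       tp·(1 − 2^(−x/ga))                       tp, ga
exp5       tp·(1 − 2^(−(x/ga)^p))                   tp, ga, p
========== ======================================== ==================

Amplitude parameters (``a``/``tp``) are signed: every form is linear in
its amplitude, so allowing negative values covers response suppression
(sub-baseline activity) with the same parameter space as refitting the
mirrored curve. Potency parameters (``ga``, ``la``, ``b``) are in µM;
powers are dimensionless.
"""

from __future__ import annotations

import numpy as np

from .errors import AimeshiftError

MODEL_NAMES: tuple[str, ...] = (
    "constant", "linear", "quadratic", "power", "hill",
    "gain_loss", "exp2", "exp3", "exp4", "exp5",
)

_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "constant": (),
    "linear": ("a",),
    "quadratic": ("a", "b"),
    "power": ("a", "p"),
    "hill": ("tp", "ga", "p"),
    "gain_loss": ("tp", "ga", "p", "la", "q"),
    "exp2": ("a", "b"),
    "exp3": ("a", "b", "p"),
    "exp4": ("tp", "ga"),
    "exp5": ("tp", "ga", "p"),
}

_EXP_CLIP = 50.0  # bounded exponent keeps overflow out of the optimizer


def model_param_names(model_name: str) -> tuple[str, ...]:
    try:
        return _PARAM_NAMES[model_name]
    except KeyError:
        raise AimeshiftError(f"unknown model {model_name!r}") from None


def eval_model(model_name: str, params: dict[str, float], x) -> np.ndarray:
    """Evaluate a named model at concentrations ``x`` (µM, > 0)."""
    x = np.asarray(x, float)
    p = params
    if model_name == "constant":
        return np.zeros_like(x)
    if model_name == "linear":
        return p["a"] * x
    if model_name == "quadratic":
        u = x / p["b"]
        return p["a"] * (u + u * u)
    if model_name == "power":
        return p["a"] * np.power(x, p["p"])
    if model_name == "hill":
        return p["tp"] / (1.0 + np.power(p["ga"] / x, p["p"]))
    if model_name == "gain_loss":
        gain = 1.0 + np.power(p["ga"] / x, p["p"])
        loss = 1.0 + np.power(x / p["la"], p["q"])
        return p["tp"] / (gain * loss)
    if model_name == "exp2":
        return p["a"] * (np.exp(np.minimum(x / p["b"], _EXP_CLIP)) - 1.0)
    if model_name == "exp3":
        return p["a"] * (np.exp(np.minimum(np.power(x / p["b"], p["p"]), _EXP_CLIP)) - 1.0)
    if model_name == "exp4":
        return p["tp"] * (1.0 - np.power(2.0, -x / p["ga"]))
    if model_name == "exp5":
        return p["tp"] * (1.0 - np.power(2.0, -np.power(x / p["ga"], p["p"])))
    raise AimeshiftError(f"unknown model {model_name!r}")


def eval_model_vector(model_name: str, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Positional-parameter evaluation (order of :func:`model_param_names`)."""
    names = model_param_names(model_name)
    return eval_model(model_name, dict(zip(names, theta)), x)


def model_bounds(
    model_name: str, conc: np.ndarray, resp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Box bounds for a model's parameters given the observed series.

    Potencies live in [cmin/100, cmax·100], powers in [0.3, 8], and the
    signed amplitude within 1.2 × 10 × max|resp| of zero.
    """
    cmin, cmax = float(np.min(conc)), float(np.max(conc))
    amax = float(np.max(np.abs(resp))) if np.any(resp) else 1.0
    amp = 1.2 * 10.0 * max(amax, 1e-6)
    pot_lo, pot_hi = cmin / 100.0, cmax * 100.0
    pw_lo, pw_hi = 0.3, 8.0
    per_param = {
        "a": (-amp, amp),
        "tp": (-amp, amp),
        "b": (pot_lo, pot_hi),
        "ga": (pot_lo, pot_hi),
        "la": (pot_lo, pot_hi),
        "p": (pw_lo, pw_hi),
        "q": (pw_lo, pw_hi),
    }
    names = model_param_names(model_name)
    lo = np.array([per_param[n][0] for n in names])
    hi = np.array([per_param[n][1] for n in names])
    return lo, hi


def model_starts(
    model_name: str,
    conc: np.ndarray,
    resp: np.ndarray,
    rng: np.random.Generator,
    n_deterministic: int = 5,
    n_random: int = 5,
) -> list[np.ndarray]:
    """Multi-start initial points: data-quantile seeds plus random draws.

    Deterministic starts anchor the amplitude at the extreme observed
    response (both signs) and potencies at concentration quantiles; random
    starts draw amplitudes uniformly and potencies log-uniformly within
    the bounds from a caller-supplied seeded generator.
    """
    names = model_param_names(model_name)
    if not names:
        return [np.empty(0)]
    lo, hi = model_bounds(model_name, conc, resp)
    cmin, cmax = float(np.min(conc)), float(np.max(conc))
    cmed = float(np.exp(np.median(np.log(conc))))
    # signed extreme response as amplitude anchor
    amax = float(resp[np.argmax(np.abs(resp))]) if np.any(resp) else 0.01
    if amax == 0.0:
        amax = 0.01

    def clamp(theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, lo, hi)

    anchors = {
        "a_at": {"linear": amax / cmax, "quadratic": amax / 2.0,
                 "power": amax / cmax, "exp2": amax / (np.e - 1.0),
                 "exp3": amax / (np.e - 1.0)},
    }
    det: list[np.ndarray] = []
    for k in range(n_deterministic):
        sign = 1.0 if k % 2 == 0 else -1.0
        pot = [cmed, cmax, cmin * 3.0, cmed * 5.0, cmax / 3.0][k % 5]
        vals = []
        for n in names:
            if n in ("tp",):
                vals.append(sign * abs(amax) * (1.0 + 0.2 * k))
            elif n == "a":
                vals.append(sign * abs(anchors["a_at"].get(model_name, amax)) * (1.0 + 0.2 * k))
            elif n in ("ga", "b"):
                vals.append(pot)
            elif n == "la":
                vals.append(cmax * 2.0)
            elif n == "p":
                vals.append(1.2)
            elif n == "q":
                vals.append(2.0)
        det.append(clamp(np.array(vals, float)))

    rand: list[np.ndarray] = []
    for _ in range(n_random):
        vals = []
        for n, l, h in zip(names, lo, hi):
            if n in ("a", "tp"):
                vals.append(rng.uniform(-2.0 * abs(amax), 2.0 * abs(amax)))
            elif n in ("ga", "la", "b"):
                vals.append(float(np.exp(rng.uniform(np.log(l), np.log(h)))))
            else:
                vals.append(rng.uniform(0.3, 4.0))
        rand.append(clamp(np.array(vals, float)))
    return det + rand


def model_jacobian(model_name: str, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian df/dθ, shape (len(x), len(θ)).

    Parameter order matches :func:`model_param_names`. Exponential forms
    use the same bounded exponent as :func:`eval_model`, so the Jacobian
    is zero past the clip (the optimizer cannot exploit the plateau).
    """
    x = np.asarray(x, float)
    ln2 = np.log(2.0)
    if model_name == "linear":
        (a,) = theta
        return x[:, None]
    if model_name == "quadratic":
        a, b = theta
        u = x / b
        return np.stack([u + u * u, -a * u * (1.0 + 2.0 * u) / b], axis=1)
    if model_name == "power":
        a, p = theta
        xp = np.power(x, p)
        return np.stack([xp, a * xp * np.log(x)], axis=1)
    if model_name == "hill":
        tp, ga, p = theta
        g = np.power(ga / x, p)
        D = 1.0 + g
        invD2 = 1.0 / (D * D)
        return np.stack(
            [1.0 / D, -tp * invD2 * p * g / ga, -tp * invD2 * g * np.log(ga / x)],
            axis=1,
        )
    if model_name == "gain_loss":
        tp, ga, p, la, q = theta
        g = np.power(ga / x, p)
        l = np.power(x / la, q)
        DG, DL = 1.0 + g, 1.0 + l
        base = 1.0 / (DG * DL)
        return np.stack(
            [
                base,
                -tp * p * g / (ga * DG * DG * DL),
                -tp * g * np.log(ga / x) / (DG * DG * DL),
                tp * q * l / (la * DG * DL * DL),
                -tp * l * np.log(x / la) / (DG * DL * DL),
            ],
            axis=1,
        )
    if model_name == "exp2":
        a, b = theta
        u = np.minimum(x / b, _EXP_CLIP)
        eu = np.exp(u)
        inside = (x / b) < _EXP_CLIP
        return np.stack([eu - 1.0, np.where(inside, -a * eu * u / b, 0.0)], axis=1)
    if model_name == "exp3":
        a, b, p = theta
        u_raw = np.power(x / b, p)
        u = np.minimum(u_raw, _EXP_CLIP)
        eu = np.exp(u)
        inside = u_raw < _EXP_CLIP
        return np.stack(
            [
                eu - 1.0,
                np.where(inside, -a * eu * p * u / b, 0.0),
                np.where(inside, a * eu * u * np.log(x / b), 0.0),
            ],
            axis=1,
        )
    if model_name == "exp4":
        tp, ga = theta
        v = x / ga
        tv = np.power(2.0, -v)
        return np.stack([1.0 - tv, -tp * tv * ln2 * v / ga], axis=1)
    if model_name == "exp5":
        tp, ga, p = theta
        v = np.power(x / ga, p)
        tv = np.power(2.0, -v)
        return np.stack(
            [1.0 - tv, -tp * tv * ln2 * p * v / ga, tp * tv * ln2 * v * np.log(x / ga)],
            axis=1,
        )
    raise AimeshiftError(f"unknown or non-differentiable model {model_name!r}")
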