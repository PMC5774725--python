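"""Independent reference implementations used only to check the package.

These deliberately re-derive results by a different route than the code
under test: a hand-written IRLS + coordinate-descent elastic-net solver,
brute-force pairwise AUC, and a textbook one-way ANOVA.
"""

import numpy as np


def elastic_net_logit_cd(z, y, alpha, lam, max_iter=2000, tol=1e-12):
    """Coordinate-descent solution of the penalized logistic objective.

    Minimizes (1/n) sum log(1 + exp(-eta*y~)) + lam*[(1-alpha)/2 ||b||^2
    + alpha ||b||_1] with an unpenalized intercept, via iteratively
    reweighted least squares with an inner coordinate-descent loop and
    soft thresholding.  ``z`` must already be standardized.
    """
    n, p = z.shape
    beta = np.zeros(p)
    beta0 = np.log(y.mean() / (1 - y.mean()))
    for _ in range(max_iter):
        eta = beta0 + z @ beta
        pr = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(pr * (1 - pr), 1e-8, None)
        work = eta + (y - pr) / w
        beta_old = beta.copy()
        beta0_old = beta0
        for _inner in range(200):
            b_prev = beta.copy()
            resid = work - beta0 - z @ beta
            for j in range(p):
                rj = resid + z[:, j] * beta[j]
                rho = np.sum(w * z[:, j] * rj) / n
                denom = np.sum(w * z[:, j] ** 2) / n + lam * (1 - alpha)
                bj = np.sign(rho) * max(abs(rho) - lam * alpha, 0.0) / denom
                resid = rj - z[:, j] * bj
                beta[j] = bj
            beta0 = np.sum(w * (work - z @ beta)) / np.sum(w)
            if np.max(np.abs(beta - b_prev)) < tol:
                break
        if max(np.max(np.abs(beta - beta_old)), abs(beta0 - beta0_old)) < 1e-10:
            break
    return beta0, beta


def auc_all_pairs(scores, labels):
    """AUC by exhaustive pair counting, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (pos.size * neg.size)


def anova_oneway(groups):
    """Textbook one-way ANOVA F statistic and degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w
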