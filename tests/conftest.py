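import numpy as np
import pandas as pd
import pytest

# ---------------------------------------------------------------------------
# published group counts: (present & STAS+, absent & STAS+, present & STAS-,
# absent & STAS-) for each binary CT feature in a 48/62 cohort
TABLE1_COUNTS = {
    "sex": (15, 33, 19, 43),                    # male = present
    "smoking": (11, 37, 10, 52),
    "location": (27, 21, 41, 21),               # upper/middle lobe = present
    "interface": (4, 44, 9, 53),                # blurry interface = present
    "morph_irregularity": (13, 35, 4, 58),
    "spiculation": (19, 29, 19, 43),
    "lobulation": (39, 9, 39, 23),
    "pleural_indentation": (32, 16, 24, 38),
    "vascular_convergence": (33, 15, 28, 34),
    "vacuole": (13, 35, 14, 48),
    "air_bronchogram": (23, 25, 22, 40),
}

N_POS, N_NEG = 48, 62


def make_table1_cohort(seed: int = 0) -> pd.DataFrame:
    """Deterministic 110-patient cohort whose 2x2 feature-vs-label tables
    reproduce the published counts exactly (continuous columns are filler)."""
    rng = np.random.default_rng(seed)
    n = N_POS + N_NEG
    stas = np.array([1] * N_POS + [0] * N_NEG)
    data = {"patient_id": [f"P{i:04d}" for i in range(n)], "stas": stas}
    for name, (a, b, c, d) in TABLE1_COUNTS.items():
        assert a + b == N_POS and c + d == N_NEG
        data[name] = np.concatenate([
            np.repeat([1, 0], [a, b]), np.repeat([1, 0], [c, d]),
        ])
    data["age"] = rng.normal(60.6, 8.0, n).round(1)
    data["ctr"] = rng.uniform(0, 100, n).round(2)
    data["fd2d"] = rng.normal(1.36, 0.09, n)
    data["fd3d"] = rng.normal(3.4, 0.2, n)
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def table1_cohort() -> pd.DataFrame:
    return make_table1_cohort()


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)

def brute_force_box_count(occ: np.ndarray, s: int) -> int:
    """Triple (or double) nested loop over grid cells of edge s."""
    count = 0
    if occ.ndim == 3:
        nz, ny, nx = occ.shape
        for i in range(0, nz, s):
            for j in range(0, ny, s):
                for k in range(0, nx, s):
                    if occ[i:i + s, j:j + s, k:k + s].any():
                        count += 1
    else:
        ny, nx = occ.shape
        for j in range(0, ny, s):
            for k in range(0, nx, s):
                if occ[j:j + s, k:k + s].any():
                    count += 1
    return count


def pairwise_auc(scores, labels) -> float:
    """Concordant-pair AUC: wins + half ties over all +/- pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def mann_whitney_u_bruteforce(x1, x2) -> float:
    u = 0.0
    for a in np.asarray(x1, dtype=float):
        for b in np.asarray(x2, dtype=float):
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    from scipy.stats import hypergeom

    n = a + b + c + d
    row1, col1 = a + c, a + b
    rv = hypergeom(n, col1, row1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)
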