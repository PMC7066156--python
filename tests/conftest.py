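import numpy as np
import pandas as pd
import pytest

from quantherit import pedigree_io


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_tables(tmp_path):
    """Two parents + two children, one exam each; minimal valid input files."""
    ped = tmp_path / "pedigree.tsv"
    ped.write_text(
        "individual_id\tfather_id\tmother_id\tsex\tcohort\n"
        "F1\t\t\tM\toffspring\n"
        "M1\t\t\tF\toffspring\n"
        "C1\tF1\tM1\tM\tgen3\n"
        "C2\tF1\tM1\tF\tgen3\n"
    )
    ex = tmp_path / "exams.tsv"
    ex.write_text(
        "individual_id\texam_index\tage\tvalue\ton_lipid_meds\n"
        "F1\t1\t52.0\t2.1\t0\n"
        "M1\t1\t50.0\t1.4\t0\n"
        "C1\t1\t27.0\t1.8\t0\n"
        "C2\t1\t25.0\t1.2\t0\n"
    )
    return ped, ex


@pytest.fixture()
def family_values():
    """Adjusted values and pedigree for a hand-checkable 3-family layout.

    fam A: both parents measured, 2 children; fam B: only mother measured,
    1 child; fam C: both parents, 3 children (sibship of 3).
    """
    ped = pd.DataFrame(
        [
            ("FA", "", "", "M", "offspring"),
            ("MA", "", "", "F", "offspring"),
            ("A1", "FA", "MA", "M", "gen3"),
            ("A2", "FA", "MA", "F", "gen3"),
            ("FB", "", "", "M", "offspring"),
            ("MB", "", "", "F", "offspring"),
            ("B1", "FB", "MB", "F", "gen3"),
            ("FC", "", "", "M", "offspring"),
            ("MC", "", "", "F", "offspring"),
            ("C1", "FC", "MC", "M", "gen3"),
            ("C2", "FC", "MC", "M", "gen3"),
            ("C3", "FC", "MC", "F", "gen3"),
        ],
        columns=["individual_id", "father_id", "mother_id", "sex", "cohort"],
    )
    values = {
        "FA": 1.0, "MA": 2.0, "A1": 1.5, "A2": 2.5,
        "MB": 3.0, "B1": 2.0,          # FB unmeasured
        "FC": 0.5, "MC": 1.5, "C1": 1.0, "C2": 2.0, "C3": 3.0,
    }
    adjusted = pd.DataFrame(
        {"individual_id": list(values), "value": list(values.values())}
    )
    return adjusted, ped


def lp_quantile_oracle(x, y, w, tau):
    """Independent LP solve of the weighted quantile regression (HiGHS).

    Returns (intercept, slope, objective).  Used only as a test oracle.
    """
    from scipy.optimize import linprog

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    n = len(x)
    c = np.concatenate([[0, 0, 0, 0], w * tau, w * (1 - tau)])
    A = np.zeros((n, 4 + 2 * n))
    A[:, 0] = 1.0
    A[:, 1] = -1.0
    A[:, 2] = x
    A[:, 3] = -x
    A[np.arange(n), 4 + np.arange(n)] = 1.0
    A[np.arange(n), 4 + n + np.arange(n)] = -1.0
    res = linprog(c, A_eq=A, b_eq=y, bounds=[(0, None)] * (4 + 2 * n), method="highs")
    assert res.status == 0
    return res.x[0] - res.x[1], res.x[2] - res.x[3], res.fun


def weighted_check_objective(x, y, w, tau, intercept, slope):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    u = y - intercept - slope * x
    return float(np.sum(w * u * (tau - (u < 0))))
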