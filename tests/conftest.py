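from __future__ import annotations

import sys
from pathlib import Path
from typing import Tuple

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from oracles import Instance  # noqa: E402

from structscan.scan import ScanTables  # noqa: E402


def random_instance(
    rng: np.random.Generator,
    n_max: int = 10,
    m_max: int = 6,
    affine: bool = True,
) -> Tuple[Instance, ScanTables]:
    """A random tiny scan problem in both oracle and engine representations.

    Sequence similarities are letter-based (as in the engine); the oracle
    receives them expanded per position pair.
    """
    n = int(rng.integers(3, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    residues = "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))
    gamma = -int(rng.integers(40, 160))
    gap_open = -int(rng.integers(100, 500)) if (affine and rng.random() < 0.5) else 0
    L = int(rng.integers(2, n + 1)) if rng.random() < 0.5 else n

    sigma_mat = rng.integers(-200, 300, size=(5, m + 1)).astype(np.int64)
    sigma_mat[4, :] = 0  # N carries no evidence
    sigma_mat[:, 0] = 0

    tpairs = {}
    for _ in range(int(rng.integers(0, 3))):
        if n < 2:
            break
        i = int(rng.integers(1, n))
        j = int(rng.integers(i + 1, n + 1))
        if j - i <= L and (i, j) not in tpairs:
            tpairs[(i, j)] = int(rng.integers(-100, 400))
    qpairs = {}
    for _ in range(int(rng.integers(0, 3))):
        if m < 2:
            break
        k = int(rng.integers(1, m))
        l = int(rng.integers(k + 1, m + 1))
        if (k, l) not in qpairs:
            qpairs[(k, l)] = int(rng.integers(-100, 400))

    qp_list = sorted(qpairs)
    tau_tab = rng.integers(-200, 300, size=(5, 5, len(qp_list))).astype(np.int64)
    tau_tab[4, :, :] = 0
    tau_tab[:, 4, :] = 0

    nt = {c: i for i, c in enumerate("ACGUN")}
    sigma_exp = {
        (i, k): int(sigma_mat[nt[residues[i - 1]], k])
        for i in range(1, n + 1)
        for k in range(1, m + 1)
    }
    tau_exp = {}
    for (i, j) in tpairs:
        for qi, (k, l) in enumerate(qp_list):
            tau_exp[(i, j, k, l)] = int(
                tau_tab[nt[residues[i - 1]], nt[residues[j - 1]], qi]
            )

    inst = Instance(
        n=n, m=m, tpairs=tpairs, qpairs=qpairs, sigma=sigma_exp, tau=tau_exp,
        gamma=gamma, gap_open=gap_open, L=L,
    )
    tables = ScanTables(
        residues=residues,
        tpairs=[(i, j, p) for (i, j), p in sorted(tpairs.items())],
        qpairs=[(k, l, p) for (k, l), p in sorted(qpairs.items())],
        sigma_mat=sigma_mat,
        tau_tab=tau_tab,
        gamma=gamma,
        gap_open=gap_open,
        L=L,
        m=m,
    )
    return inst, tables


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
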