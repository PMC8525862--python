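import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spodium import synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CORPUS_SEED = 2024


# --- independent scalar geometry, used to audit the package's results -------

def oracle_distance(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def oracle_angle(a, v, c):
    u1 = [x - y for x, y in zip(a, v)]
    u2 = [x - y for x, y in zip(c, v)]
    dot = sum(x * y for x, y in zip(u1, u2))
    n1 = math.sqrt(sum(x * x for x in u1))
    n2 = math.sqrt(sum(x * x for x in u2))
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))


def oracle_contact_scan(model, d_min=2.5, d_max=5.0, angle_min=140.0,
                        coord_cutoff=2.5):
    """Brute-force (zn, acceptor) serial pairs satisfying the criteria."""
    heavy = [a for a in model.atoms if not a.is_hydrogen]
    pairs = set()
    for zn in heavy:
        if zn.element != "Zn":
            continue
        shell = [
            a for a in heavy
            if a.element in ("N", "O", "S")
            and oracle_distance(a.coords, zn.coords) < coord_cutoff
        ]
        if len(shell) != 4:
            continue
        shell_ids = {id(a) for a in shell}
        for acc in heavy:
            if acc.element not in ("N", "O", "S") or id(acc) in shell_ids:
                continue
            d = oracle_distance(acc.coords, zn.coords)
            if not (d_min <= d < d_max):
                continue
            theta = max(
                oracle_angle(lig.coords, zn.coords, acc.coords) for lig in shell
            )
            if angle_min <= theta <= 180.0:
                pairs.add((zn.serial, acc.serial))
    return pairs


@pytest.fixture(scope="session")
def corpus():
    """Seed-fixed 50-structure synthetic corpus with ground truth."""
    return synthetic.generate_corpus(50, seed=CORPUS_SEED)


@pytest.fixture
def simple_site_spec():
    """One 3HIS+1ASP site with a single planted water contact."""
    return synthetic.SyntheticSpec(
        sites=[["HIS-N", "HIS-N", "HIS-N", "ASP-O"]],
        acceptors=[
            synthetic.PlannedAcceptor("O", "water", 3.5, 170.0, 0, 0)
        ],
        seed=42,
    )


def rigid_transform(model, seed=0):
    """Apply a random rotation + translation to every atom in place."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-50, 50, size=3)
    for a in model.atoms:
        a.coords = Q @ a.coords + t
    return model
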