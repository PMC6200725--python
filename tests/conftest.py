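import numpy as np
import pandas as pd
import pytest

from eealineage import CohortConfig, SurvivalConfig, generate_cohort


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """A fast cohort with every planted signal class present."""
    kwargs = dict(
        n_normal=20,
        n_tumor_per_stage=(15, 15, 15),
        n_genes=300,
        n_early_burst=20,
        n_late=30,
        n_down=20,
        n_cna_driven=10,
        effect_log2=2.0,
        penetrance=0.9,
        noise_sd=0.5,
        n_clusters=4,
        survival=SurvivalConfig(),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def tumor_normal_ids(small_cohort):
    s = small_cohort.samples
    return (
        s.loc[s["group"] == "tumor", "sample"].tolist(),
        s.loc[s["group"] == "normal", "sample"].tolist(),
    )


def random_additive_matrix(rng: np.random.Generator, n_taxa: int) -> pd.DataFrame:
    """Leaf-to-leaf distances of a random tree with positive branch lengths.

    Built by repeatedly joining two active subtrees with fresh positive
    edges, accumulating each leaf's distance to its subtree root; the
    resulting matrix is exactly additive by construction.
    """
    names = [f"L{i}" for i in range(n_taxa)]
    dist = pd.DataFrame(0.0, index=names, columns=names)
    active: list[dict[str, float]] = [{nm: 0.0} for nm in names]
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        ea, eb = rng.uniform(0.5, 3.0, size=2)
        for la, da in a.items():
            for lb, db in b.items():
                d = da + ea + eb + db
                dist.loc[la, lb] = d
                dist.loc[lb, la] = d
        merged = {la: da + ea for la, da in a.items()}
        merged.update({lb: db + eb for lb, db in b.items()})
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [merged]
    return dist
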