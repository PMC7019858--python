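import numpy as np
import pandas as pd
import pytest

from staygreen import synthetic_data as sd


@pytest.fixture(scope="session")
def small_panel():
    """40-cultivar balanced panel with a planted yield trend."""
    cfg = sd.PanelConfig(
        n_cultivars=40,
        trait_means={"yield": 8.0},
        trait_slopes={"yield": 0.04},
        var_components={"yield": (0.3, 0.2, 0.02, 0.02, 0.6)},
        seed=42,
    )
    return sd.simulate_panel(cfg)


@pytest.fixture(scope="session")
def structured_genotypes():
    """5-group genotype panel with a planted causal region on 6A."""
    cfg = sd.PanelConfig(
        n_cultivars=100,
        trait_means={"gcd": 330.0},
        trait_slopes={"gcd": 0.0},
        var_components={"gcd": (100.0, 0.0, 0.0, 0.0, 50.0)},
        seed=5,
    )
    panel = sd.simulate_panel(cfg)
    gcfg = sd.GenoSimConfig(
        n_markers=1200,
        n_groups=5,
        missing_rate=0.02,
        causal_region=("6A", 400.0, 442.0, -25.0),
        seed=5,
    )
    geno = sd.simulate_genotypes(gcfg, panel)
    panel = sd.apply_causal_effect(panel, geno, "gcd")
    return panel, geno


@pytest.fixture()
def toy_blues():
    """12 hand-listed cultivars with release years and one trait."""
    years = [1966, 1970, 1975, 1980, 1985, 1990, 1995, 2000, 2003, 2006, 2010, 2013]
    vals = [5.0, 5.2, 5.1, 5.6, 5.8, 6.1, 6.0, 6.5, 6.7, 6.9, 7.2, 7.4]
    return pd.DataFrame(
        {
            "cultivar": [f"cv{i:02d}" for i in range(12)],
            "year_of_release": years,
            "trait": "yield",
            "blue": vals,
            "season": np.nan,
        }
    )


def ems_oracle(panel: pd.DataFrame, trait: str) -> dict:
    """Henderson expected-mean-squares estimator for a balanced
    cultivar x season x rep table under y = mu + c + cy + e.

    Independent of the package's REML path (pure array arithmetic).
    """
    df = panel[panel["trait"] == trait]
    wide = df.pivot_table(index="cultivar", columns=["season", "rep"], values="value")
    n_c = wide.shape[0]
    n_s = df["season"].nunique()
    n_r = df["rep"].nunique()
    arr = wide.to_numpy().reshape(n_c, n_s, n_r)
    cell = arr.mean(axis=2)
    cv = cell.mean(axis=1)
    ms_c = n_s * n_r * ((cv - arr.mean()) ** 2).sum() / (n_c - 1)
    ms_cell = n_r * ((cell - cv[:, None]) ** 2).sum() / (n_c * (n_s - 1))
    mse = ((arr - cell[:, :, None]) ** 2).sum() / (n_c * n_s * (n_r - 1))
    return {
        "sigma2_e": mse,
        "sigma2_cy": max((ms_cell - mse) / n_r, 0.0),
        "sigma2_c": max((ms_c - ms_cell) / (n_s * n_r), 0.0),
    }
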