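import numpy as np
import pandas as pd
import pytest

from fluctinvade import grid_to_csv, make_example_model, mip_grid, pip_grid

C11, C22, C21 = 1.0, 2.0, -1.5


def analytic_s(x, y):
    return C11 * x * x + C22 * y * y + 2.0 * C21 * x * y


def test_pip_signs_match_the_fitness_function():
    spec = make_example_model("analytic")
    pip = pip_grid(spec, (-0.6, 0.6), 7, method="closed_form")
    for i, x in enumerate(pip.x_grid):
        for j, y in enumerate(pip.y_grid):
            s = analytic_s(x, y)
            assert pip.S_values[i, j] == pytest.approx(s, abs=1e-12)
            if i == j or abs(s) <= 1e-10:
                assert pip.region[i, j] == "neutral_band"
            else:
                assert pip.region[i, j] == ("plus" if s > 0 else "minus")


def test_diagonal_is_always_neutral():
    spec = make_example_model("analytic")
    pip = pip_grid(spec, (-1.0, 1.0), 9)
    assert all(pip.region[i, i] == "neutral_band" for i in range(9))


def test_mutual_invasibility_combines_transposed_cells():
    spec = make_example_model("analytic")
    pip = pip_grid(spec, (-0.6, 0.6), 7)
    mip = mip_grid(pip)
    for i in range(7):
        for j in range(7):
            both = (pip.region[i, j], pip.region[j, i])
            if both == ("plus", "plus"):
                assert mip[i, j] == "mutual"
            elif "plus" in both:
                assert mip[i, j] == "one_way"
            else:
                assert mip[i, j] == "none"
    # symmetry of the mutual region
    assert np.array_equal(mip == "mutual", (mip == "mutual").T)


def test_grid_requires_at_least_two_points():
    spec = make_example_model("analytic")
    with pytest.raises(ValueError):
        pip_grid(spec, (0.0, 1.0), 1)


def test_chemostat_invasion_region_matches_resource_threshold():
    """Mutant invades iff gamma' beta' E[R] > delta' + D with
    E[R] = (delta + D)/(gamma beta): sweeping uptake beta alone, the plus
    region is exactly beta_mutant > beta_resident."""
    spec = make_example_model("chemostat")
    slice_fn = lambda u: np.array([u, 0.8, 0.095])
    pip = pip_grid(spec, (1.0, 3.0), 9, method="closed_form",
                   strategy_slice=slice_fn)
    for i in range(9):
        for j in range(9):
            if i == j:
                assert pip.region[i, j] == "neutral_band"
            else:
                expected = "plus" if pip.y_grid[j] > pip.x_grid[i] else "minus"
                assert pip.region[i, j] == expected


def test_long_format_export(tmp_path):
    spec = make_example_model("analytic")
    pip = pip_grid(spec, (-0.5, 0.5), 4)
    path = tmp_path / "pip.csv"
    grid_to_csv(pip, path, mip=mip_grid(pip))
    df = pd.read_csv(path)
    assert len(df) == 16
    assert {"x", "y", "S", "se", "region", "mip_region"} <= set(df.columns)
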