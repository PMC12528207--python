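import numpy as np
import pytest


def ols_oracle(x, y):
    """Brute-force normal-equations simple regression, independent of the
    package's lstsq path: explicit 2x2 solve from raw sums.

    Returns (slope, intercept, r2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    pred = intercept + slope * x
    sst = ((y - y.mean()) ** 2).sum()
    sse = ((y - pred) ** 2).sum()
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return slope, intercept, r2


@pytest.fixture
def mx_file(tmp_path):
    """Write HMD-style Mx text content and return its path."""

    def _write(body, header="Year          Age             Total", preamble=True):
        text = ""
        if preamble:
            text += "Testland, Death rates (period 1x5)\n\n"
        text += header + "\n" + body
        path = tmp_path / "mx.txt"
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def rotation_fits():
    """Noise-free rotation pipeline: simulate, fit all periods, fit SM."""
    from smrotation import default_spec, simulate_surface, fit_all_periods, fit_sm

    output = simulate_surface(default_spec())
    fits = fit_all_periods(output.surface)
    return output, fits, fit_sm(fits)
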