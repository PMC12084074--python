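import numpy as np
import pandas as pd
import pytest

from smnmeth.types import CpGSite, MethylationMatrix, SampleMeta


def make_matrix(percent: np.ndarray, chrom: str = "chr5", start: int = 71_375_100,
                spacing: int = 50, depth: int | np.ndarray = 1000,
                samples: list[str] | None = None) -> MethylationMatrix:
    """Assemble a MethylationMatrix from a raw percent array (NaN ok)."""
    percent = np.asarray(percent, dtype=float)
    n_sites, n_samples = percent.shape
    positions = [start + i * spacing for i in range(n_sites)]
    index = pd.Index([f"{chrom}:{p}" for p in positions], name="site_id")
    samples = samples or [f"S{j + 1:03d}" for j in range(n_samples)]
    if np.isscalar(depth):
        depth_arr = np.full_like(percent, depth, dtype=int)
        depth_arr[np.isnan(percent)] = 0
    else:
        depth_arr = np.asarray(depth, dtype=int)
    sites = pd.DataFrame(
        {"chrom": chrom, "c_pos": positions, "region": None,
         "members": [[sid] for sid in index]},
        index=index,
    )
    return MethylationMatrix(
        percent=pd.DataFrame(percent, index=index, columns=samples),
        depth=pd.DataFrame(depth_arr, index=index, columns=samples),
        sites=sites,
    )


def make_sample(i: int, **kw) -> SampleMeta:
    defaults = dict(
        sample_id=f"S{i:03d}", sex="female" if i % 2 else "male",
        age_at_sampling=20.0 + i, sma_type=2, sma_subtype="a", smn2_cn=3,
        gqn=7.0, library_size_per_smn_copy=1e4,
    )
    defaults.update(kw)
    return SampleMeta(**defaults)


@pytest.fixture
def cpg_sites():
    return [CpGSite("chr5", 71_375_100 + 50 * i) for i in range(4)]


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
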