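import numpy as np
import pandas as pd
import pytest

from temposel.data import GenotypeMatrix


def marker_map(n_markers, n_chrom=1, spacing=1000):
    rows = []
    per = np.full(n_chrom, n_markers // n_chrom)
    per[: n_markers % n_chrom] += 1
    for c, m in enumerate(per, start=1):
        for i in range(m):
            rows.append((f"m{c}_{i + 1}", f"chr{c}", (i + 1) * spacing,
                         i + 1, "A/C"))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "index",
                                       "alleles"])


def genotype_matrix(calls, n_chrom=1, line_ids=None, panel_extra=None):
    calls = np.asarray(calls, dtype=np.int8)
    markers = marker_map(calls.shape[1], n_chrom)
    ids = line_ids or [f"L{i + 1}" for i in range(calls.shape[0])]
    panel = pd.DataFrame({"line_id": ids})
    if panel_extra:
        for k, v in panel_extra.items():
            panel[k] = v
    return GenotypeMatrix(calls, markers, panel)


@pytest.fixture
def hapmap_path(tmp_path):
    """3 lines x 6 markers, one chromosome, all biallelic A/C."""
    lines = [
        "rs\tchrom\tpos\talleles\tL1\tL2\tL3",
        "m1\tchr1\t100\tA/C\tAA\tCC\tAC",
        "m2\tchr1\t200\tA/C\tAA\tAA\tNN",
        "m3\tchr1\t300\tA/C\tCC\tCC\tCC",
        "m4\tchr1\t400\tA/C\tAA\tCC\tAA",
        "m5\tchr1\t500\tA/C\tCC\tAA\tAA",
        "m6\tchr1\t600\tA/C\tAA\tAA\tCC",
    ]
    p = tmp_path / "geno.tsv"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
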