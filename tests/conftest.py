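import numpy as np
import pytest

from meiorepair.assay import PHENOTYPE_CLASSES, WINDOWS, ProgenyRecord


def make_progeny_records(recombinants_per_window, genotype="wt",
                         nonrecombinant=100, n_parents=2):
    """Records whose per-window recombinant totals (NCO+CO) match the given
    four totals, split across parents."""
    records = []
    for w, total in zip(WINDOWS, recombinants_per_window):
        per_parent = np.array_split(np.arange(total), n_parents)
        for i, chunk in enumerate(per_parent):
            k = len(chunk)
            counts = dict.fromkeys(PHENOTYPE_CLASSES, 0)
            counts["NCO_recombinant"] = k - k // 3
            counts["CO_recombinant"] = k // 3
            counts["nonrecombinant"] = nonrecombinant
            records.append(ProgenyRecord(genotype, "r1", f"p{i}", w, counts))
    return records


@pytest.fixture
def wt_records():
    # wild-type per-window recombinant totals from the ICR assay
    return make_progeny_records((28, 25, 22, 15), genotype="wt")


@pytest.fixture
def brc1_records():
    return make_progeny_records((24, 43, 36, 9), genotype="brc-1")
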