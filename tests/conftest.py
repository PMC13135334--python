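import numpy as np
import pytest

from aacsia import Dataset, SampleRecord


def make_record(sample_id="S1", distance_km=None, tow_depth_m=None,
                habitat=None, d13c=None, d15n=None, sd=0.0, n_reps=1):
    """Build a SampleRecord from {aa: value} dicts per isotope system."""
    rec = SampleRecord(sample_id=sample_id, distance_km=distance_km,
                       tow_depth_m=tow_depth_m, habitat=habitat)
    for aa, v in (d13c or {}).items():
        rec.set(aa, "d13C", v, sd=sd, n_reps=n_reps)
    for aa, v in (d15n or {}).items():
        rec.set(aa, "d15N", v, sd=sd, n_reps=n_reps)
    return rec


@pytest.fixture
def toy_dataset():
    """Five samples with complete 6-EAA d13C and Glx/Ala/Phe/Lys d15N."""
    rng = np.random.default_rng(42)
    records = []
    for i in range(5):
        base = rng.uniform(-26, -18)
        d13c = {aa: base + rng.normal(0, 1)
                for aa in ("Ile", "Leu", "Lys", "Phe", "Thr", "Val")}
        phe = rng.uniform(2, 8)
        d15n = {"Phe": phe, "Lys": phe - 0.2,
                "Glx": phe + 3.4 + 7.6 * 1.3, "Ala": phe + 3.2 + 4.5 * 1.3}
        records.append(make_record(f"S{i + 1}", distance_km=float(2 ** i),
                                   tow_depth_m=10.0 * (i + 1),
                                   d13c=d13c, d15n=d15n, sd=0.42, n_reps=3))
        records[-1].assign_habitat_from_metadata()
    return Dataset(records=records)
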