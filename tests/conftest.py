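import datetime as dt

import numpy as np
import pytest

from yamcross import PollinationRecord, SimulationConfig


@pytest.fixture
def record():
    def make(**kw):
        base = dict(
            date=dt.date(2019, 8, 5),
            site="ibadan",
            female_accession="TDr001",
            male_accession="TDr002",
            female_species="d. rotundata",
            male_species="d. rotundata",
            flowers_pollinated=20,
            fruits_set=5,
            viable_seeds=12,
            pollinator_id="P01",
        )
        base.update(kw)
        return PollinationRecord(**base)

    return make


@pytest.fixture
def records_csv(tmp_path):
    path = tmp_path / "records.csv"
    path.write_text(
        "date,site,pollinator_id,female_accession,male_accession,"
        "female_species,male_species,flowers_pollinated,fruits_set,viable_seeds\n"
        "2019-08-05,ibadan,P01,TDr001,TDr002,D. rotundata,D. rotundata,20,5,12\n"
        "2019-08-06,ibadan,P01,TDr001,TDr002,D. rotundata,D. rotundata,10,2,4\n"
        "2019-10-12,abuja,P02,TDa001,TDr002,D. alata,D. rotundata,30,1,\n"
    )
    return path


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=7,
        n_females=6,
        n_males=6,
        combinations_per_species=15,
        batches_per_combination=2,
        n_loci=200,
        n_interspecific=4,
        n_families=40,
        seeds_per_family=30,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
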