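import datetime as dt

import pytest

from brackish.core_io import TaxonCountTable, TaxonRow, WaterSample
from brackish.synthetic import ScenarioSpec


def make_table(counts, source="water", sample_id="s1", fish_length_cm=None,
               fish_weight_g=None):
    """Build a TaxonCountTable from {genus: (phylum, count)}."""
    rows = [TaxonRow(genus=g, phylum=p, count=c) for g, (p, c) in counts.items()]
    return TaxonCountTable(source=source, sample_id=sample_id, rows=rows,
                           fish_length_cm=fish_length_cm,
                           fish_weight_g=fish_weight_g)


@pytest.fixture
def default_spec():
    return ScenarioSpec(rng_seed=0)


@pytest.fixture
def water_fixture():
    """Six hand-written water samples across two seasons and three sites."""
    base = dict(no3_n=0.05, no2_n=0.008, nh4=0.06, po4_p=0.3, dsi=5.0, chla=3.0)
    rows = []
    for i, (site, season, month, temp, sal, do, ph) in enumerate([
            ("UE-1", "dry", 1, 22.0, 0.5, 8.4, 7.1),
            ("UE-2", "dry", 2, 22.4, 0.6, 8.3, 7.2),
            ("ME-1", "dry", 12, 22.7, 6.5, 8.3, 7.3),
            ("UE-1", "wet", 7, 31.2, 0.2, 6.9, 6.8),
            ("UE-2", "wet", 8, 30.9, 0.3, 6.8, 7.0),
            ("ME-1", "wet", 10, 30.4, 0.2, 6.8, 7.4)]):
        rows.append(WaterSample(
            station_id=site.split("-")[0], site_id=site,
            date=dt.date(2020 if month >= 7 else 2021, month, 15),
            season=season, temperature=temp, salinity=sal, do=do, ph=ph,
            **base))
    return rows
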