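import pytest

from bevan_severity import (DepotMetadata, EnvironmentRecord, SurveyRecord)


def make_record(depot="1a", year=2015, month=7, species="Arhopalus rusticus",
                family="Cerambycidae", count=1, source="pheromone_trap",
                life_stage="adult") -> SurveyRecord:
    return SurveyRecord(depot_code=depot, year=year, month=month,
                        species=species, family=family, count=count,
                        life_stage=life_stage, source=source)


def make_depot(code="1a", province="DU", distance="lt_3km") -> DepotMetadata:
    return DepotMetadata(depot_code=code, province=province, aspect="E",
                         altitude_m=100, distance_class=distance,
                         forest_type="coniferous")


@pytest.fixture
def tiny_survey():
    """Two species at two depots over three months; hand-enumerable."""
    return [
        make_record(depot="1a", month=7, count=5),
        make_record(depot="1a", month=8, count=1),
        make_record(depot="1b", month=7, count=2),
        make_record(depot="1a", month=7, species="Thanasimus formicarius",
                    family="Cleridae", count=3),
    ]


@pytest.fixture
def two_depots():
    return [make_depot("1a", "DU", "lt_3km"), make_depot("1b", "DU", "gt_3km")]


@pytest.fixture
def flat_env():
    """Environment covering both depots, April-October 2015, constant-ish."""
    out = []
    for depot in ("1a", "1b"):
        for month in range(4, 11):
            out.append(EnvironmentRecord(depot_code=depot, year=2015,
                                         month=month, mean_temp_c=10.0 + month,
                                         mean_rh_pct=70.0))
    return out
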