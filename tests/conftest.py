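import pandas as pd
import pytest

from pestiscore import data_io


@pytest.fixture
def conc_csv(tmp_path):
    """Write a concentration CSV from a list of row dicts and return its path."""

    def _write(rows, name="conc.csv", columns=None):
        path = tmp_path / name
        df = pd.DataFrame(rows, columns=columns)
        df.to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def toy_rows():
    """Three well-formed monitoring rows (one per pattern: detect, non-detect, mg/L)."""
    return [
        {"country": "CHN", "water_body": "surface", "site_id": "s1",
         "pesticide_cas": "1912-24-9", "pesticide_name": "atrazine",
         "concentration": 0.5, "unit": "ug/L", "detected": "true",
         "lod": "", "loq": "", "year_start": 2015},
        {"country": "China", "water_body": "surface", "site_id": "s2",
         "pesticide_cas": "1912-24-9", "pesticide_name": "atrazine",
         "concentration": "", "unit": "ug/L", "detected": "false",
         "lod": 0.01, "loq": "", "year_start": 2016},
        {"country": "USA", "water_body": "ground", "site_id": "g1",
         "pesticide_cas": "94-75-7", "pesticide_name": "2,4-D",
         "concentration": 0.005, "unit": "mg/L", "detected": "true",
         "lod": "", "loq": "", "year_start": 2012},
    ]
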