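import pytest

import eventstore as es


@pytest.fixture
def cfg(tmp_path):
    config = es.DatabaseConfig(name="dbtest", base_dir=tmp_path)
    es.create_database(config)
    return config


@pytest.fixture
def conn(cfg):
    handle = es.connect(cfg)
    yield handle
    if handle.is_open:
        handle.close()


def dump_all(conn):
    """Full contents of every table, for before/after comparisons."""
    out = {}
    for table in conn.table_names():
        cols = conn.columns(table, include_blobs=True)
        cur = conn._raw_execute(
            f"SELECT {', '.join(cols)} FROM {table} ORDER BY {cols[0]}"
        )
        out[table] = cur.fetchall()
    return out


@pytest.fixture
def small_eeg():
    spec = es.SyntheticSpec(n_channels=4, n_frames=1000, srate=100.0,
                            n_events=10, n_event_types=3,
                            event_attr_fields=2, seed=7)
    return es.generate_eeg(spec)
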