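import pytest

from bedvalue import table2_fixture


@pytest.fixture()
def worked_example():
    """The built-in three-group case mix with P_1 chosen."""
    return table2_fixture()


@pytest.fixture()
def chosen(worked_example):
    case_mix, _ = worked_example
    return case_mix.resolve_chosen()


@pytest.fixture()
def second_best(worked_example):
    case_mix, _ = worked_example
    return case_mix.group("P_2")


@pytest.fixture()
def context(worked_example):
    return worked_example[1]
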