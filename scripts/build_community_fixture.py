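"""Regenerate the packaged community-model TSVs from the fixture builder.

Run from the repository root:

    python scripts/build_community_fixture.py
"""

from pathlib import Path

from syntrophyflux.fixture import PROTEOME_SHARES, build_community_model
from syntrophyflux.network import CommunityModel

OUT = Path(__file__).resolve().parent.parent / "src" / "syntrophyflux" / "data" / "community"


def main() -> None:
    model = build_community_model()
    model.proteome_shares = {
        g: s / sum(PROTEOME_SHARES.values()) for g, s in PROTEOME_SHARES.items()
    }
    model.to_tsvs(OUT)
    reloaded = CommunityModel.from_tsvs(OUT, name="community")
    assert reloaded.summary()["n_reactions"] == model.summary()["n_reactions"]
    reloaded.check_mass_balance()
    print(f"wrote {OUT} ({model.summary()})")


if __name__ == "__main__":
    main()
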