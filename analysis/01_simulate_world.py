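"""Generate the synthetic study world and its banding records.

Builds an 8-species, 6-year world (weekly abundance surfaces drifting between
breeding and nonbreeding ranges, AR(1) geomagnetic and solar index series,
species traits) plus map-level fall banding records, and writes the full
fixture bundle for the downstream steps.
"""

from pathlib import Path

from vgm.synthetic import (
    TruthParams,
    WorldConfig,
    gen_banding_records,
    gen_world,
    write_fixture_bundle,
)

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

CONFIG = WorldConfig(n_species=8, n_years=6, seed=20250921 % 2**20)
TRUTH = TruthParams()


def main() -> None:
    world = gen_world(CONFIG)
    records, truth = gen_banding_records(
        world, TRUTH, n_per_species_year=40, mode="spatial", seed=CONFIG.seed + 1
    )
    bundle = SCRATCH / "world_bundle"
    write_fixture_bundle(world, records, truth, bundle)
    print(f"world: {CONFIG.n_species} species x {CONFIG.n_years} years, "
          f"{len(world.surfaces)} weekly surfaces")
    print(f"records: {len(records)} fall captures "
          f"({(records['age_class'] == 'unknown').mean():.0%} unknown age)")
    print(f"geomagnetic index mean {world.geomag.values.mean():.1f}, "
          f"solar mean {world.solar.values.mean():.1f}")
    print(f"bundle written to {bundle}")


if __name__ == "__main__":
    main()
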