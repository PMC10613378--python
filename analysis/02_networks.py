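"""Build the shared-patient physician network and the shared-physician
hospital network from billing records, and export both."""

import argparse
from pathlib import Path

from peernet.metrics import degree, density
from peernet.network import (
    Window,
    attribute_physicians,
    binarize,
    build_encounter_matrix,
    build_hospital_network,
    project_shared_patients,
    read_billing,
    write_edge_list,
    write_graphml,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--billing", default="results/data/billing.csv")
    ap.add_argument("--a-low", type=float, default=0.0)
    ap.add_argument("--out", default="results/networks")
    args = ap.parse_args()

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    billing = read_billing(args.billing)
    A = project_shared_patients(build_encounter_matrix(billing))
    B = binarize(A, args.a_low)
    write_graphml(A.physicians, A.weights, outdir / "physician_network.graphml")
    write_edge_list(A.physicians, A.weights, outdir / "physician_network_edges.csv")
    print(f"physician network: {len(A.physicians)} nodes, {B.n_edges()} edges "
          f"at a_low={args.a_low}, density {density(B):.4f}, "
          f"mean degree {degree(B).mean():.2f}")

    hosp = build_hospital_network(billing, Window("2020-03-01", "2021-05-31"))
    write_edge_list(hosp.hospitals, hosp.edges, outdir / "hospital_network_edges.csv")
    n_edges = (hosp.edges > 0).sum() // 2
    print(f"hospital network (pandemic window): {len(hosp.hospitals)} hospitals, "
          f"{n_edges} connected pairs")


if __name__ == "__main__":
    main()
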