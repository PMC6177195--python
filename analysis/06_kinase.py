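#!/usr/bin/env python
"""Filter kinase-substrate predictions and confirm pairs in the network.

GPS predictions are kept at differential score >= 1.0 (score minus cutoff,
inclusive) and NetworKIN predictions at score > 2.0 (strict). A prediction is
confirmed when its kinase-substrate pair is also a physical interactome edge;
the count is restricted to module members.
"""

from pathlib import Path

from ppimod.kinase_substrate import confirmed_table
from ppimod.pipeline import Pipeline, PipelineConfig

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    pipe = Pipeline(PipelineConfig.from_yaml(out / "pipeline_config.yaml"))
    result = pipe.kinase
    confirmed_table(result["confirmed"]).to_csv(
        out / "kinase_confirmed.tsv", sep="\t", index=False)
    print(f"{result['n_filtered_predictions']} predictions pass the score filters")
    print(f"{result['n_substrates_confirmed']} of {len(pipe.module_genes)} module "
          f"substrates have >= 1 kinase interaction confirmed in the network")


if __name__ == "__main__":
    main()
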