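{
  "schema_version": "1",
  "comment": "Pairwise co-application constraints between predictive and functional evidence codes. Symmetric; forbidden dominates when sources disagree. Pairs not listed are unrestricted.",
  "pairs": [
    {"a": "PP3", "b": "PS3|BS3", "status": "allowed"},
    {"a": "PP3", "b": "PS1", "status": "allowed"},
    {"a": "PP3", "b": "PVS1", "status": "forbidden"},
    {"a": "PP3", "b": "PVS1(RNA)", "status": "forbidden"},
    {"a": "PP3", "b": "BP4", "status": "not_applicable"},
    {"a": "PP3", "b": "BP7", "status": "forbidden"},
    {"a": "PP3", "b": "BP7(RNA)", "status": "allowed"},
    {"a": "PS3|BS3", "b": "PS1", "status": "not_applicable"},
    {"a": "PS3|BS3", "b": "PVS1", "status": "allowed"},
    {"a": "PS3|BS3", "b": "PVS1(RNA)", "status": "allowed"},
    {"a": "PS3|BS3", "b": "BP4", "status": "allowed"},
    {"a": "PS3|BS3", "b": "BP7", "status": "allowed"},
    {"a": "PS3|BS3", "b": "BP7(RNA)", "status": "allowed"},
    {"a": "PS1", "b": "PVS1", "status": "not_applicable"},
    {"a": "PS1", "b": "PVS1(RNA)", "status": "not_applicable"},
    {"a": "PS1", "b": "BP4", "status": "not_applicable"},
    {"a": "PS1", "b": "BP7", "status": "not_applicable"},
    {"a": "PS1", "b": "BP7(RNA)", "status": "not_applicable"},
    {"a": "PVS1", "b": "PVS1(RNA)", "status": "forbidden"},
    {"a": "PVS1", "b": "BP4", "status": "forbidden"},
    {"a": "PVS1", "b": "BP7", "status": "forbidden"},
    {"a": "PVS1", "b": "BP7(RNA)", "status": "forbidden"},
    {"a": "PVS1(RNA)", "b": "BP4", "status": "forbidden"},
    {"a": "PVS1(RNA)", "b": "BP7", "status": "forbidden"},
    {"a": "PVS1(RNA)", "b": "BP7(RNA)", "status": "forbidden"},
    {"a": "BP4", "b": "BP7", "status": "allowed"},
    {"a": "BP4", "b": "BP7(RNA)", "status": "allowed"},
    {"a": "BP7", "b": "BP7(RNA)", "status": "forbidden"}
  ]
}
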