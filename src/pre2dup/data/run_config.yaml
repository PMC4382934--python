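# Run configuration template. Paths are relative to this file.
global_params: params_global.yaml
atc_params: params_atc.yaml
vnr_params: params_vnr.yaml
separator: ","
max_iter: 5
# columns: maps standard names onto the input header, e.g.
#   columns: {person_id: PID, date: OSTOPV, atc: ATC}
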