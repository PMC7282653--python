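study_id,mu_ni_hat,sigma_ni,mu_h_hat,sigma_h,delta0,alpha
S014695/10-trials,-0.0036,0.0868,0.2341,0.0750,0.5,0.025
S014796/10-trials,-0.0844,0.0867,0.2341,0.0750,0.5,0.025
Pooled/10-trials,-0.0432,0.0613,0.2341,0.0750,0.5,0.025
S014695/8-trials,-0.0036,0.0868,0.2398,0.0593,0.5,0.025
S014796/8-trials,-0.0844,0.0867,0.2398,0.0593,0.5,0.025
Pooled/8-trials,-0.0432,0.0613,0.2398,0.0593,0.5,0.025
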