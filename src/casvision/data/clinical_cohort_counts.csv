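item,count,denominator
eyelid_redness,342,1020
conjunctival_redness,428,1020
eyelid_swelling,849,1020
caruncle_inflammation,123,1020
conjunctival_edema,107,1020
spontaneous_pain,109,918
gaze_pain,78,918
active_tao,272,918
highly_active_tao,34,918
missing_pain_record,102,1020
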