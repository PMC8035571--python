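needle_id,anchor_x_mm,anchor_y_mm,dir_x,dir_y,tip_x_mm,tip_y_mm,entry_x_mm,entry_y_mm,n_inliers,sigma_mm
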