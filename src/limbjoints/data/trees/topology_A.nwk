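(Pan,(A_afarensis,(A_garhi,((P_robustus,P_boisei),(A_africanus,(A_sediba,(H_habilis,(H_floresiensis,(H_erectus,(H_naledi,H_sapiens))))))))));
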