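(Cel,(Bfl,((Odi,(Bsc,(Dvex,(Cin,Csa)Ciona)Aplousostolido)Ascidiacea)Tunicata,(Pma,(Dre,(Lch,(Xtr,Aca)Tetrapoda)Sarcopterygii)Gnathostomata)Craniata)Olfactores)Chordata)Bilateria;
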